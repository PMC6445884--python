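pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0.5009	0.5923	-1.0234	-1.1434	1.3093	-0.1166	-0.1944	1.3878	-1.2215	1.1635	0.7484	0.0716	-1.5903	-0.0865	-0.9349	0.0488	0.1798	1.2137	0.9726	1.1069
2	0.5405	0.5945	-1.1022	-1.1878	1.4074	-0.1138	-0.2345	1.4297	-1.2628	1.2535	0.7851	0.0413	-1.6855	-0.0671	-0.9484	0.0444	0.1534	1.2601	1.0480	1.1874
3	0.5633	0.5940	-1.1769	-1.2275	1.5161	-0.1366	-0.2829	1.5113	-1.3035	1.3474	0.8087	0.0114	-1.7793	-0.0358	-0.9905	0.0191	0.1339	1.3468	1.1448	1.2633
4	0.5719	0.6067	-1.2414	-1.2750	1.6223	-0.1788	-0.3237	1.6344	-1.3582	1.4345	0.8281	-0.0029	-1.8721	-0.0087	-1.0684	-0.0152	0.1351	1.4688	1.2465	1.3302
5	0.5777	0.6446	-1.2988	-1.3439	1.7196	-0.2256	-0.3453	1.7874	-1.4395	1.5124	0.8573	0.0062	-1.9717	0.0004	-1.1761	-0.0423	0.1614	1.6098	1.3387	1.3926
6	0.5948	0.7095	-1.3584	-1.4410	1.8099	-0.2606	-0.3460	1.9485	-1.5511	1.5863	0.9077	0.0361	-2.0872	-0.0143	-1.2966	-0.0495	0.2062	1.7483	1.4143	1.4602
7	0.6323	0.7908	-1.4295	-1.5607	1.8994	-0.2731	-0.3340	2.0938	-1.6837	1.6646	0.9815	0.0740	-2.2215	-0.0473	-1.4076	-0.0334	0.2540	1.8649	1.4751	1.5415
8	0.6891	0.8697	-1.5145	-1.6854	1.9929	-0.2627	-0.3233	2.2044	-1.8161	1.7518	1.0687	0.1034	-2.3668	-0.0844	-1.4900	-0.0016	0.2879	1.9490	1.5283	1.6367
9	0.7532	0.9261	-1.6050	-1.7904	2.0878	-0.2392	-0.3262	2.2721	-1.9227	1.8433	1.1503	0.1119	-2.5032	-0.1095	-1.5342	0.0309	0.2969	1.9999	1.5806	1.7352
10	0.8057	0.9468	-1.6833	-1.8531	2.1719	-0.2174	-0.3470	2.2995	-1.9818	1.9247	1.2050	0.0963	-2.6048	-0.1116	-1.5424	0.0490	0.2805	2.0242	1.6321	1.8174
11	0.8294	0.9306	-1.7284	-1.8611	2.2264	-0.2101	-0.3797	2.2956	-1.9841	1.9762	1.2181	0.0646	-2.6483	-0.0904	-1.5253	0.0440	0.2488	2.0301	1.6745	1.8616
12	0.8156	0.8881	-1.7246	-1.8165	2.2328	-0.2215	-0.4101	2.2698	-1.9347	1.9796	1.1872	0.0319	-2.6215	-0.0561	-1.4960	0.0183	0.2177	2.0213	1.6933	1.8530
13	0.7683	0.8363	-1.6681	-1.7344	2.1809	-0.2454	-0.4226	2.2267	-1.8505	1.9272	1.1231	0.0133	-2.5287	-0.0246	-1.4633	-0.0160	0.2008	1.9955	1.6742	1.7898
14	0.7024	0.7911	-1.5698	-1.6363	2.0745	-0.2681	-0.4078	2.1646	-1.7530	1.8253	1.0449	0.0171	-2.3891	-0.0101	-1.4278	-0.0428	0.2038	1.9451	1.6104	1.6845
15	0.6374	0.7603	-1.4510	-1.5417	1.9311	-0.2752	-0.3668	2.0783	-1.6592	1.6932	0.9722	0.0405	-2.2302	-0.0184	-1.3835	-0.0494	0.2214	1.8634	1.5070	1.5600
16	0.5894	0.7414	-1.3359	-1.4609	1.7768	-0.2584	-0.3117	1.9647	-1.5768	1.5564	0.9174	0.0711	-2.0781	-0.0445	-1.3218	-0.0328	0.2404	1.7498	1.3810	1.4408
17	0.5643	0.7240	-1.2429	-1.3935	1.6373	-0.2201	-0.2600	1.8275	-1.5033	1.4381	0.8813	0.0934	-1.9491	-0.0747	-1.2388	-0.0008	0.2464	1.6137	1.2559	1.3443
18	0.5568	0.6962	-1.1784	-1.3309	1.5295	-0.1726	-0.2276	1.6797	-1.4301	1.3508	0.8552	0.0953	-1.8467	-0.0933	-1.1391	0.0316	0.2308	1.4732	1.1532	1.2758
19	0.5536	0.6515	-1.1364	-1.2634	1.4565	-0.1327	-0.2212	1.5404	-1.3498	1.2936	0.8261	0.0746	-1.7629	-0.0902	-1.0360	0.0491	0.1955	1.3496	1.0848	1.2284
20	0.5408	0.5930	-1.1033	-1.1869	1.4090	-0.1139	-0.2361	1.4290	-1.2616	1.2550	0.7847	0.0397	-1.6860	-0.0656	-0.9472	0.0436	0.1517	1.2600	1.0496	1.1883
21	0.5110	0.5324	-1.0656	-1.1060	1.3714	-0.1207	-0.2587	1.3576	-1.1734	1.2195	0.7302	0.0059	-1.6073	-0.0299	-0.8876	0.0175	0.1158	1.2108	1.0351	1.1433
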