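aa	freq
A	0.0500
C	0.0030
D	0.0220
E	0.0220
F	0.0290
G	0.0840
H	0.0190
I	0.0220
K	0.0240
L	0.0380
M	0.0170
N	0.1870
P	0.0520
Q	0.2020
R	0.0210
S	0.0920
T	0.0410
V	0.0250
W	0.0050
Y	0.0450
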