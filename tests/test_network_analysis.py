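from collections import deque

import networkx as nx
import numpy as np
import pytest

from prionscape._validation import ValidationError
from prionscape.network_analysis import (analyze_set, collapse_to_genes,
                                         intra_set_edges, lcc_size,
                                         load_edge_list,
                                         mean_shortest_distance, network_null,
                                         set_degree_stats)
from prionscape.synthetic_data import generate_interactome


# --- independent oracles ----------------------------------------------------

class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def lcc_oracle(graph, members):
    present = [m for m in members if m in graph]
    uf = UnionFind(present)
    mset = set(present)
    for a, b in graph.edges():
        if a in mset and b in mset:
            uf.union(a, b)
    from collections import Counter
    return max(Counter(uf.find(m) for m in present).values())


def bfs_distances(graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nb in graph.adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def msd_oracle(graph, members):
    present = [m for m in members if m in graph]
    values = []
    for m in present:
        dist = bfs_distances(graph, m)
        others = [dist[o] for o in present if o != m and o in dist]
        if others:
            values.append(min(others))
    return float(np.mean(values)) if values else float("nan")


@pytest.fixture(scope="module")
def random_graph():
    return generate_interactome(150, 0.03, seed=8)


class TestCollapseToGenes:
    def test_injective_mapping(self):
        mapping = {f"P{i}": f"G{i}" for i in range(10)}
        genes, unmapped = collapse_to_genes(mapping.keys(), mapping)
        assert len(genes) == 10 and unmapped == 0

    def test_isoforms_collapse(self):
        genes, _ = collapse_to_genes(["P1a", "P1b"],
                                     {"P1a": "G1", "P1b": "G1"})
        assert genes == {"G1"}

    def test_unmapped_dropped_and_counted(self):
        genes, unmapped = collapse_to_genes(["P1", "P2"], {"P1": "G1"})
        assert genes == {"G1"} and unmapped == 1

    def test_grouping_oracle(self, rng):
        proteins = [f"P{i}" for i in range(200)]
        mapping = {p: f"G{rng.integers(50)}" for p in proteins}
        genes, _ = collapse_to_genes(proteins, mapping)
        assert genes == set(mapping.values())


class TestDegreeStats:
    def test_isolated_node_included(self):
        g = nx.Graph()
        g.add_node("a")
        g.add_edge("b", "c")
        degrees, mean = set_degree_stats(g, {"a", "b"})
        assert sorted(degrees) == [0.0, 1.0] and mean == 0.5

    def test_star_center(self):
        g = nx.star_graph(10)
        degrees, _ = set_degree_stats(g, {0})
        assert degrees[0] == 10

    def test_absent_genes_excluded(self, random_graph):
        degrees, _ = set_degree_stats(random_graph,
                                      {"G00001", "NOT_IN_GRAPH"})
        assert degrees.size == 1

    def test_empty_intersection_rejected(self, random_graph):
        with pytest.raises(ValidationError):
            set_degree_stats(random_graph, {"NOPE"})

    def test_adjacency_count_oracle(self, random_graph, rng):
        members = list(rng.choice(sorted(random_graph.nodes), size=30,
                                  replace=False))
        degrees, mean = set_degree_stats(random_graph, members)
        expected = sorted(len(random_graph.adj[m]) for m in members)
        assert sorted(degrees) == expected
        assert mean == pytest.approx(np.mean(expected))


class TestIntraSetEdges:
    def test_singleton_zero(self, random_graph):
        assert intra_set_edges(random_graph, {"G00001"}) == 0

    def test_clique(self):
        g = nx.complete_graph(5)
        assert intra_set_edges(g, set(range(5))) == 10

    def test_edge_filter_oracle(self, random_graph, rng):
        members = set(rng.choice(sorted(random_graph.nodes), size=40,
                                 replace=False))
        expected = sum(1 for a, b in random_graph.edges()
                       if a in members and b in members)
        assert intra_set_edges(random_graph, members) == expected


class TestLCC:
    def test_edgeless_induced_subgraph(self):
        g = nx.path_graph(5)
        assert lcc_size(g, {0, 2, 4}) == 1

    def test_path_through_all_members(self):
        g = nx.path_graph(6)
        assert lcc_size(g, set(range(6))) == 6

    def test_union_find_oracle(self, rng):
        for seed in range(20):
            g = generate_interactome(int(rng.integers(20, 200)), 0.04,
                                     seed=seed)
            members = list(rng.choice(sorted(g.nodes),
                                      size=int(rng.integers(5, 15)),
                                      replace=False))
            assert lcc_size(g, members) == lcc_oracle(g, members)


class TestMSD:
    def test_adjacent_pair(self):
        g = nx.Graph([("a", "b")])
        assert mean_shortest_distance(g, {"a", "b"}) == 1.0

    def test_full_graph_paths_used(self):
        # set members mutually non-adjacent but linked through an outside hub
        g = nx.Graph([("a", "hub"), ("b", "hub"), ("c", "hub")])
        assert mean_shortest_distance(g, {"a", "b", "c"}) == 2.0

    def test_unreachable_members_excluded(self):
        g = nx.Graph([("a", "b")])
        g.add_edge("c", "d")
        g.add_node("e")
        # e has no reachable partner; a-b at 1; c-d at 1
        assert mean_shortest_distance(g, {"a", "b", "c", "d", "e"}) == 1.0

    def test_all_isolated_sentinel(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        assert np.isnan(mean_shortest_distance(g, {"a", "b"}))

    def test_too_few_members_rejected(self, random_graph):
        with pytest.raises(ValidationError):
            mean_shortest_distance(random_graph, {"G00001"})

    def test_bfs_oracle(self, rng):
        for seed in range(20):
            g = generate_interactome(int(rng.integers(30, 200)), 0.03,
                                     seed=100 + seed)
            members = list(rng.choice(sorted(g.nodes),
                                      size=int(rng.integers(5, 20)),
                                      replace=False))
            result = mean_shortest_distance(g, members)
            oracle = msd_oracle(g, members)
            if np.isnan(oracle):
                assert np.isnan(result)
            else:
                assert result == pytest.approx(oracle)


class TestNetworkNull:
    def test_constant_statistic_sentinel(self, random_graph):
        result = network_null(random_graph, 10,
                              lambda g, s: float(len(list(s))),
                              n_samples=50, seed=0, observed=10.0)
        assert np.isnan(result.z)

    def test_random_set_not_significant(self, random_graph):
        rng = np.random.default_rng(42)
        exceed = 0
        replicates = 50
        for i in range(replicates):
            members = list(rng.choice(sorted(random_graph.nodes), size=20,
                                      replace=False))
            result = network_null(
                random_graph, 20, lambda g, s: float(lcc_size(g, s)),
                n_samples=300, seed=1000 + i, observed_set=members,
            )
            if abs(result.z) >= 3:
                exceed += 1
        assert exceed <= 2

    def test_planted_module_detected(self):
        module = [f"G{i + 1:05d}" for i in range(60)]
        g = generate_interactome(800, 0.004, module=module, p_module=0.12,
                                 seed=3)
        lcc = network_null(g, 60, lambda gr, s: float(lcc_size(gr, s)),
                           n_samples=300, seed=1, observed_set=module)
        msd = network_null(g, 60, mean_shortest_distance,
                           n_samples=300, seed=2, observed_set=module)
        assert lcc.z > 3
        assert msd.z < -1

    def test_z_uses_sample_sd(self, random_graph):
        result = network_null(random_graph, 15,
                              lambda g, s: float(lcc_size(g, s)),
                              n_samples=200, seed=9,
                              observed=5.0)
        null = result.null_samples
        expected_z = (5.0 - null.mean()) / null.std(ddof=1)
        assert result.z == pytest.approx(expected_z)


class TestAnalyzeSet:
    def test_full_stats_bundle(self, random_graph):
        members = sorted(random_graph.nodes)[:25]
        stats_obj = analyze_set(random_graph, members, n_samples=100, seed=0)
        assert stats_obj.n_in_graph == 25
        assert stats_obj.lcc_size <= 25
        assert stats_obj.intra_edges <= 25 * 24 // 2
        assert stats_obj.msd >= 1 or np.isnan(stats_obj.msd)
        assert set(stats_obj.resampling) <= {"mean_degree", "intra_edges",
                                             "lcc_size", "msd"}
        assert 0 <= stats_obj.degree_wilcoxon_p <= 1

    def test_determinism(self, random_graph):
        members = sorted(random_graph.nodes)[:20]
        a = analyze_set(random_graph, members, n_samples=50, seed=4)
        b = analyze_set(random_graph, members, n_samples=50, seed=4)
        assert a.to_dict() == b.to_dict()


class TestEdgeListIO:
    def test_roundtrip(self, tmp_path, random_graph):
        from prionscape.synthetic_data import write_edges_tsv
        path = tmp_path / "edges.tsv"
        write_edges_tsv(random_graph, path)
        loaded = load_edge_list(path)
        assert sorted(map(tuple, map(sorted, loaded.edges()))) == \
            sorted(map(tuple, map(sorted, random_graph.edges())))

    def test_self_loops_dropped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("id_a\tid_b\na\tb\na\ta\n")
        g = load_edge_list(path)
        assert sorted(g.edges()) == [("a", "b")]
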