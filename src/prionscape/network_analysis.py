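"""Interactome statistics for a gene set against random-set nulls.

For a set of genes mapped into an undirected simple interaction graph the
module measures mean degree, intra-set edge count, the largest connected
component (LCC) of the induced subgraph, and the mean shortest distance
(MSD): for each set member, the full-graph shortest-path distance to its
nearest other set member, averaged over members with at least one reachable
partner.  Each statistic is compared to draws of random node sets of the
same size (default 1000) via Z-score and empirical p.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import stats

from ._resampling import ResamplingResult, resampled_null
from ._validation import ValidationError, check

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSetStats",
    "load_edge_list",
    "collapse_to_genes",
    "set_degree_stats",
    "intra_set_edges",
    "lcc_size",
    "mean_shortest_distance",
    "network_null",
    "analyze_set",
]


def load_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph
    (self-loops dropped, duplicate edges collapsed)."""
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["id_a", "id_b"]:  # headerless file: first line is an edge
            if len(header) >= 2:
                graph.add_edge(header[0], header[1])
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] != parts[1]:
                graph.add_edge(parts[0], parts[1])
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def collapse_to_genes(
    protein_ids: Iterable[str], mapping: dict[str, str]
) -> tuple[set[str], int]:
    """Map protein ids onto distinct gene ids; returns (gene set, number of
    proteins without a mapping).  Unmapped ids are logged and dropped."""
    genes = set()
    unmapped = 0
    for pid in protein_ids:
        if pid in mapping:
            genes.add(mapping[pid])
        else:
            unmapped += 1
    if unmapped:
        logger.info("collapse_to_genes: %d protein ids lacked a gene mapping",
                    unmapped)
    return genes, unmapped


def _present(graph: nx.Graph, gene_set: Iterable[str]) -> list[str]:
    return [g for g in gene_set if g in graph]


def set_degree_stats(graph: nx.Graph, gene_set: Iterable[str]
                     ) -> tuple[np.ndarray, float]:
    """Degrees of set members present in the graph plus their mean."""
    present = _present(graph, set(gene_set))
    if not present:
        raise ValidationError("gene_set: no member is a node of the graph")
    degrees = np.array([graph.degree[g] for g in sorted(present)], dtype=float)
    return degrees, float(degrees.mean())


def intra_set_edges(graph: nx.Graph, gene_set: Iterable[str]) -> int:
    members = set(gene_set)
    return sum(1 for a, b in graph.edges() if a in members and b in members)


def lcc_size(graph: nx.Graph, gene_set: Iterable[str]) -> int:
    """Largest connected component of the subgraph induced by set members
    present in the graph (1 for an edgeless non-empty induced subgraph)."""
    present = _present(graph, set(gene_set))
    if not present:
        raise ValidationError("gene_set: no member is a node of the graph")
    sub = graph.subgraph(present)
    return max(len(cc) for cc in nx.connected_components(sub))


def _nearest_member_distance(adjacency: dict, source, targets: set) -> int | None:
    """Early-terminating BFS: distance from source to the nearest node in
    ``targets`` (source excluded); None if unreachable."""
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, dist = frontier.popleft()
        for nb in adjacency[node]:
            if nb in seen:
                continue
            if nb in targets:
                return dist + 1
            seen.add(nb)
            frontier.append((nb, dist + 1))
    return None


def mean_shortest_distance(graph: nx.Graph, gene_set: Iterable[str]) -> float:
    """Mean over set members of the full-graph distance to the nearest other
    set member; members with no reachable partner are excluded (logged);
    NaN when every member is isolated from the rest of the set."""
    present = sorted(_present(graph, set(gene_set)))
    if len(present) < 2:
        raise ValidationError("gene_set: need >= 2 members mapped into the graph")
    adjacency = {n: list(graph.adj[n]) for n in graph.nodes}
    member_set = set(present)
    distances = []
    excluded = 0
    for g in present:
        d = _nearest_member_distance(adjacency, g, member_set - {g})
        if d is None:
            excluded += 1
        else:
            distances.append(d)
    if excluded:
        logger.debug("mean_shortest_distance: %d members had no reachable partner",
                     excluded)
    if not distances:
        return float("nan")
    return float(np.mean(distances))


def network_null(
    graph: nx.Graph,
    set_size: int,
    statistic,
    n_samples: int = 1000,
    seed: int | None = None,
    observed: float | None = None,
    observed_set: Iterable[str] | None = None,
) -> ResamplingResult:
    """Statistic of the observed set against ``n_samples`` uniform draws of
    ``set_size`` nodes (without replacement); NaN draws excluded and counted."""
    nodes = sorted(graph.nodes)
    if observed is None:
        check(observed_set is not None,
              "observed/observed_set: one of the two must be given")
        observed = float(statistic(graph, observed_set))
    return resampled_null(
        nodes, set_size, lambda sample: statistic(graph, sample), observed,
        n_samples=n_samples, seed=seed,
    )


@dataclass
class NetworkSetStats:
    n_in_graph: int
    n_unmapped: int
    mean_degree: float
    intra_edges: int
    lcc_size: int
    msd: float
    resampling: dict[str, ResamplingResult]
    degree_wilcoxon_p: float

    def to_dict(self) -> dict:
        return {
            "n_in_graph": self.n_in_graph,
            "n_unmapped": self.n_unmapped,
            "mean_degree": self.mean_degree,
            "intra_edges": self.intra_edges,
            "lcc_size": self.lcc_size,
            "msd": self.msd,
            "degree_wilcoxon_p": self.degree_wilcoxon_p,
            "resampling": {k: v.to_dict() for k, v in self.resampling.items()},
        }


_STATISTICS = {
    "mean_degree": lambda g, s: set_degree_stats(g, s)[1],
    "intra_edges": lambda g, s: float(intra_set_edges(g, s)),
    "lcc_size": lambda g, s: float(lcc_size(g, s)),
    "msd": lambda g, s: mean_shortest_distance(g, s),
}


def analyze_set(
    graph: nx.Graph,
    gene_set: Iterable[str],
    n_samples: int = 1000,
    seed: int | None = None,
) -> NetworkSetStats:
    """All four statistics with their resampling nulls, plus a rank-sum test
    of member degrees against pooled null-member degrees."""
    gene_set = set(gene_set)
    present = _present(graph, gene_set)
    check(bool(present), "gene_set: no member is a node of the graph")
    degrees, mean_degree = set_degree_stats(graph, present)
    observed = {
        "mean_degree": mean_degree,
        "intra_edges": float(intra_set_edges(graph, present)),
        "lcc_size": float(lcc_size(graph, present)),
        "msd": mean_shortest_distance(graph, present)
        if len(present) >= 2 else float("nan"),
    }
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0])
                   for name, s in zip(sorted(_STATISTICS), ss.spawn(len(_STATISTICS) + 1))}
    resampling = {}
    for name, func in _STATISTICS.items():
        if np.isnan(observed[name]):
            continue
        resampling[name] = network_null(
            graph, len(present), func, n_samples=n_samples,
            seed=stage_seeds[name], observed=observed[name],
        )
    # rank-sum of observed member degrees vs degrees of random-null members
    rng = np.random.default_rng(int(ss.spawn(1)[0].generate_state(1)[0]))
    nodes = sorted(graph.nodes)
    pooled = []
    for _ in range(min(n_samples, 100)):
        draw = rng.choice(nodes, size=len(present), replace=False)
        pooled.extend(graph.degree[n] for n in draw)
    wilcoxon_p = float(stats.ranksums(degrees, pooled).pvalue) if pooled else float("nan")
    return NetworkSetStats(
        n_in_graph=len(present),
        n_unmapped=len(gene_set) - len(present),
        mean_degree=mean_degree,
        intra_edges=int(observed["intra_edges"]),
        lcc_size=int(observed["lcc_size"]),
        msd=observed["msd"],
        resampling=resampling,
        degree_wilcoxon_p=wilcoxon_p,
    )


def write_stats_json(stats_obj: NetworkSetStats, path: str | Path) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(stats_obj.to_dict()), fh, indent=1, allow_nan=False)
        fh.write("\n")
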