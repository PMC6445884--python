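"""Generators for every pipeline input, with recorded ground truth.

Each generator is deterministic given its parameters and seed, returns an
in-memory object carrying both the data and the planted truth, and has a
matching ``write_*`` function emitting the standard text format plus a truth
sidecar TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._validation import ValidationError, check
from .prld_detection import AMINO_ACIDS, CompositionModel

__all__ = [
    "PlantedDomain",
    "SyntheticProteome",
    "SyntheticTruth",
    "ExpressionData",
    "generate_proteome",
    "generate_annotations",
    "generate_expression",
    "generate_disease_labels",
    "generate_interactome",
    "simulate_full",
    "write_proteome_fasta",
]

# residues the planted 21-mer core is drawn from: high amyloid-propensity,
# so the embedded core scores far above the 60.00 cutoff under the shipped matrix
_CORE_RESIDUES = "FYIVML"
_FASTA_WIDTH = 62


@dataclass
class PlantedDomain:
    is_planted: bool
    start: int | None = None  # 1-based inclusive
    end: int | None = None
    placement: str | None = None  # N | C | internal


@dataclass
class SyntheticProteome:
    """(protein_id, gene_id, sequence) records plus per-protein planted truth."""

    records: list[tuple[str, str, str]]
    truth: dict[str, PlantedDomain]

    @property
    def planted_ids(self) -> list[str]:
        return [p for p, t in self.truth.items() if t.is_planted]

    @property
    def protein_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def gene_of(self) -> dict[str, str]:
        return {p: g for p, g, _ in self.records}

    def sequences(self) -> dict[str, str]:
        return {p: s for p, _, s in self.records}


@dataclass
class SyntheticTruth:
    """Ground truth planted across the non-proteome generators."""

    planted_enriched_terms: dict[str, float] = field(default_factory=dict)
    planted_cluster_labels: dict[str, int] = field(default_factory=dict)
    planted_disease_rates: tuple[float, float] | None = None
    planted_module: set[str] = field(default_factory=set)


@dataclass
class ExpressionData:
    table: pd.DataFrame  # gene x tissue, ordinal 0-3
    labels: dict[str, int]  # planted cluster index per gene


def _freq_arrays(freqs: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(AMINO_ACIDS))
    p = np.array([freqs[aa] for aa in AMINO_ACIDS], dtype=float)
    return letters, p / p.sum()


def _sample_sequence(rng: np.random.Generator, length: int,
                     freqs: dict[str, float]) -> str:
    letters, p = _freq_arrays(freqs)
    return "".join(rng.choice(letters, size=length, p=p))


def generate_proteome(
    n_proteins: int,
    prion_fraction: float,
    length_range: tuple[int, int] = (160, 450),
    terminal_bias: float = 0.8,
    seed: int | None = None,
    prld_length: int = 80,
) -> SyntheticProteome:
    """Background sequences from the shipped background composition, with
    ``round(n_proteins * prion_fraction)`` proteins carrying a planted
    Q/N-rich segment of ``prld_length`` residues that embeds one
    high-propensity 21-mer amyloid core.

    ``terminal_bias`` is the probability that a planted segment is placed at
    a terminus (N or C with equal odds) rather than inside the internal half.
    """
    check(n_proteins >= 1, "n_proteins: must be >= 1")
    if not (0.0 <= prion_fraction <= 1.0):
        raise ValidationError(f"prion_fraction: {prion_fraction} outside [0, 1]")
    if not (0.0 <= terminal_bias <= 1.0):
        raise ValidationError(f"terminal_bias: {terminal_bias} outside [0, 1]")
    lo, hi = length_range
    if lo < 80 or lo < prld_length + 20:
        raise ValidationError(
            f"length_range: lower bound {lo} too short for a planted domain "
            f"of {prld_length} residues plus flanks"
        )
    check(hi >= lo, "length_range: upper bound below lower bound")
    check(prld_length >= 60, "prld_length: planted domain must be >= 60 residues")

    rng = np.random.default_rng(seed)
    model = CompositionModel.default()
    # planting composition: prion table with Q/N boosted to 0.50 combined,
    # so realized segments clear the Q+N >= 0.35 floor enforced below
    plant_freqs = dict(model.prion_freqs)
    other = 1.0 - plant_freqs["Q"] - plant_freqs["N"]
    for aa in plant_freqs:
        if aa not in ("Q", "N"):
            plant_freqs[aa] *= 0.50 / other
    plant_freqs["Q"], plant_freqs["N"] = 0.26, 0.24
    qn_floor = int(np.ceil(0.35 * prld_length))
    n_planted = int(round(n_proteins * prion_fraction))
    planted_idx = set(
        rng.choice(n_proteins, size=n_planted, replace=False).tolist()
    ) if n_planted else set()

    records: list[tuple[str, str, str]] = []
    truth: dict[str, PlantedDomain] = {}
    core_letters = np.array(list(_CORE_RESIDUES))
    for i in range(n_proteins):
        protein_id = f"P{i + 1:05d}"
        gene_id = f"G{i + 1:05d}"
        L = int(rng.integers(lo, hi + 1))
        seq = list(_sample_sequence(rng, L, model.background_freqs))
        if i in planted_idx:
            core = rng.choice(core_letters, size=21)
            # constrain the core so every 60-residue window inside the
            # segment fully contains it (core interval within
            # [prld_length - 60, 60 - 21]); falls back to centred placement
            a_lo = max(0, prld_length - 60)
            a_hi = min(prld_length - 21, 60 - 21)
            if a_lo <= a_hi:
                core_at = int(rng.integers(a_lo, a_hi + 1))
            else:
                core_at = (prld_length - 21) // 2
            while True:
                segment = list(_sample_sequence(rng, prld_length, plant_freqs))
                segment[core_at:core_at + 21] = core
                if segment.count("Q") + segment.count("N") >= qn_floor:
                    break
            if rng.random() < terminal_bias:
                placement = "N" if rng.random() < 0.5 else "C"
            else:
                placement = "internal"
            if placement == "N":
                start = 0
            elif placement == "C":
                start = L - prld_length
            else:
                s_lo = -(-L // 4)  # ceil(L/4)
                s_hi = (3 * L) // 4 - prld_length
                start = (
                    int(rng.integers(s_lo, s_hi + 1))
                    if s_hi >= s_lo
                    else (L - prld_length) // 2
                )
            seq[start:start + prld_length] = segment
            truth[protein_id] = PlantedDomain(
                True, start + 1, start + prld_length, placement
            )
        else:
            truth[protein_id] = PlantedDomain(False)
        records.append((protein_id, gene_id, "".join(seq)))
    return SyntheticProteome(records=records, truth=truth)


def generate_annotations(
    proteome: SyntheticProteome,
    n_terms: int,
    enriched: dict[str, float] | None = None,
    seed: int | None = None,
    base_rate: float | tuple[float, float] = (0.02, 0.20),
    iea_fraction: float = 0.2,
    namespace: str = "BP",
    set_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Protein->term annotation rows with planted enrichments.

    Non-enriched terms have identical membership probability inside and
    outside the set; an enriched term's in-set membership odds equal
    background odds x its planted odds ratio.  Columns:
    ``protein_id, term_id, namespace, evidence``.
    """
    enriched = enriched or {}
    for term, odds in enriched.items():
        check(odds > 0, f"enriched: odds ratio for {term} must be > 0")
    check(0.0 <= iea_fraction <= 1.0, "iea_fraction: outside [0, 1]")
    all_ids = proteome.protein_ids
    if set_ids is None:
        in_set = set(proteome.planted_ids)
    else:
        in_set = set(set_ids)
        unknown = in_set - set(all_ids)
        if unknown:
            raise ValidationError(
                f"set_ids: unknown protein ids {sorted(unknown)[:5]}"
            )
    rng = np.random.default_rng(seed)
    terms = [f"T{i + 1:04d}" for i in range(n_terms)]
    terms += [t for t in sorted(enriched) if t not in terms]
    rows = []
    for term in terms:
        if isinstance(base_rate, tuple):
            p_bg = float(rng.uniform(*base_rate))
        else:
            p_bg = float(base_rate)
        odds_ratio = enriched.get(term, 1.0)
        odds_bg = p_bg / (1.0 - p_bg) if p_bg < 1 else np.inf
        odds_set = odds_bg * odds_ratio
        p_set = odds_set / (1.0 + odds_set) if np.isfinite(odds_set) else 1.0
        for protein_id in all_ids:
            p = p_set if protein_id in in_set else p_bg
            if rng.random() < p:
                evidence = "IEA" if rng.random() < iea_fraction else "EXP"
                rows.append((protein_id, term, namespace, evidence))
    return pd.DataFrame(
        rows, columns=["protein_id", "term_id", "namespace", "evidence"]
    )


def generate_expression(
    genes: Sequence[str],
    tissues: Sequence[str],
    k_true: int,
    effect: float,
    seed: int | None = None,
) -> ExpressionData:
    """Gene x tissue ordinal ranks (0-3) with ``k_true`` planted clusters.

    A latent standard-normal value per cell is shifted by the gene's cluster
    offset vector (entries +-``effect``) and discretized at the standard
    normal quartile cut-points, yielding ranks in {0, 1, 2, 3}.
    """
    check(k_true >= 1, "k_true: must be >= 1")
    if len(genes) < k_true:
        raise ValidationError(
            f"genes: {len(genes)} genes cannot form k_true={k_true} clusters"
        )
    rng = np.random.default_rng(seed)
    n_g, n_t = len(genes), len(tissues)
    order = rng.permutation(n_g)
    labels = np.empty(n_g, dtype=int)
    labels[order] = np.arange(n_g) % k_true
    offsets = rng.choice([-1.0, 1.0], size=(k_true, n_t)) * float(effect)
    latent = rng.standard_normal((n_g, n_t)) + offsets[labels]
    # fixed quartile cut-points of the standard normal latent scale
    cuts = np.array([-0.6744897501960817, 0.0, 0.6744897501960817])
    ranks = np.searchsorted(cuts, latent, side="left").astype(int)
    table = pd.DataFrame(ranks, index=list(genes), columns=list(tissues))
    return ExpressionData(table=table, labels=dict(zip(genes, labels.tolist())))


def generate_disease_labels(
    genes: Sequence[str],
    set_ids: Iterable[str],
    base_rate: float,
    set_rate: float,
    seed: int | None = None,
    source: str = "SYN",
) -> pd.DataFrame:
    """Bernoulli disease labels: background genes at ``base_rate``, set genes
    at ``set_rate``.  Columns: ``gene_id, disease_id, source``."""
    for name, rate in (("base_rate", base_rate), ("set_rate", set_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"{name}: {rate} outside [0, 1]")
    in_set = set(set_ids)
    unknown = in_set - set(genes)
    if unknown:
        raise ValidationError(f"set_ids: {sorted(unknown)[:5]} not in genes")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for gene in genes:
        p = set_rate if gene in in_set else base_rate
        if rng.random() < p:
            counter += 1
            rows.append((gene, f"D{counter:05d}", source))
    return pd.DataFrame(rows, columns=["gene_id", "disease_id", "source"])


def generate_interactome(
    n_nodes: int,
    p_background: float,
    module: Iterable[str] | None = None,
    p_module: float | None = None,
    seed: int | None = None,
    nodes: Sequence[str] | None = None,
):
    """Erdos-Renyi background graph with one denser planted module.

    Node pairs connect at ``p_background`` except pairs inside ``module``,
    which connect at ``p_module``.  Returns a simple undirected
    :class:`networkx.Graph`.
    """
    import networkx as nx

    if nodes is None:
        check(n_nodes >= 1, "n_nodes: must be >= 1")
        nodes = [f"G{i + 1:05d}" for i in range(n_nodes)]
    else:
        nodes = list(nodes)
        n_nodes = len(nodes)
    module = set(module) if module is not None else set()
    p_module = p_background if p_module is None else p_module
    if not (0.0 <= p_background <= p_module <= 1.0):
        raise ValidationError(
            "p_background/p_module: need 0 <= p_background <= p_module <= 1"
        )
    unknown = module - set(nodes)
    if unknown:
        raise ValidationError(f"module: {sorted(unknown)[:5]} not graph nodes")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    in_module = np.isin(np.arange(n_nodes), [i for i, nd in enumerate(nodes) if nd in module])
    p = np.where(in_module[iu] & in_module[ju], p_module, p_background)
    keep = rng.random(iu.size) < p
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    node_arr = np.array(nodes, dtype=object)
    graph.add_edges_from(zip(node_arr[iu[keep]], node_arr[ju[keep]]))
    return graph


# ---------------------------------------------------------------------------
# writers

def write_proteome_fasta(proteome: SyntheticProteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein_id, gene_id, seq in proteome.records:
            fh.write(f">{protein_id}|{gene_id}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i:i + _FASTA_WIDTH] + "\n")


def write_proteome_truth(proteome: SyntheticProteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_id\tis_planted\tstart\tend\tplacement\n")
        gene_of = proteome.gene_of
        for protein_id, t in proteome.truth.items():
            fh.write(
                f"{protein_id}\t{gene_of[protein_id]}\t{int(t.is_planted)}\t"
                f"{t.start if t.start else 'NA'}\t{t.end if t.end else 'NA'}\t"
                f"{t.placement or 'NA'}\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_edges_tsv(graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# full preset

def simulate_full(
    outdir: str | Path,
    seed: int = 0,
    n_proteins: int = 500,
    prion_fraction: float = 0.1,
    n_terms: int = 40,
    enriched: dict[str, float] | None = None,
    n_tissues: int = 30,
    k_true: int = 4,
    expression_effect: float = 1.5,
    base_disease_rate: float = 0.024,
    set_disease_rate: float = 0.13,
    p_background: float = 0.004,
    p_module: float = 0.08,
) -> SyntheticTruth:
    """Generate one coherent dataset exercising every pipeline stage and
    write all standard-format files plus truth sidecars into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(5)]
    if enriched is None:
        enriched = {"T0001": 8.0, "T0002": 4.0}

    proteome = generate_proteome(n_proteins, prion_fraction, seed=seeds[0])
    write_proteome_fasta(proteome, outdir / "proteome.fasta")
    write_proteome_truth(proteome, outdir / "proteome_truth.tsv")
    gene_of = proteome.gene_of
    planted_genes = {gene_of[p] for p in proteome.planted_ids}
    genes = [gene_of[p] for p in proteome.protein_ids]

    annotations = generate_annotations(
        proteome, n_terms=n_terms, enriched=enriched, seed=seeds[1]
    )
    write_tsv(annotations, outdir / "annotations.tsv")

    tissues = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    expression = generate_expression(genes, tissues, k_true,
                                     expression_effect, seed=seeds[2])
    expr_out = expression.table.copy()
    expr_out.index.name = "gene_id"
    write_tsv(expr_out, outdir / "expression.tsv", index=True)
    pd.DataFrame(
        sorted(expression.labels.items()), columns=["gene_id", "cluster"]
    ).to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)

    disease = generate_disease_labels(
        genes, planted_genes, base_disease_rate, set_disease_rate, seed=seeds[3]
    )
    write_tsv(disease, outdir / "disease.tsv")

    graph = generate_interactome(
        len(genes), p_background, module=planted_genes,
        p_module=p_module, seed=seeds[4], nodes=genes,
    )
    write_edges_tsv(graph, outdir / "edges.tsv")

    with open(outdir / "mapping.tsv", "w") as fh:
        fh.write("protein_id\tgene_id\n")
        for protein_id, gene_id, _ in proteome.records:
            fh.write(f"{protein_id}\t{gene_id}\n")

    truth = SyntheticTruth(
        planted_enriched_terms=dict(enriched),
        planted_cluster_labels=expression.labels,
        planted_disease_rates=(base_disease_rate, set_disease_rate),
        planted_module=planted_genes,
    )
    with open(outdir / "set_genes.txt", "w") as fh:
        for g in sorted(planted_genes):
            fh.write(g + "\n")
    with open(outdir / "background_genes.txt", "w") as fh:
        for g in genes:
            fh.write(g + "\n")
    return truth
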