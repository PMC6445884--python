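"""Disease-association fraction of a gene set against an empirical null of
random same-size background samples (default 100, as plotted against the
95th percentile)."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from ._resampling import ResamplingResult, resampled_null
from ._validation import check

logger = logging.getLogger(__name__)

__all__ = [
    "load_disease_table",
    "disease_fraction",
    "disease_resampling",
    "enrichment_ratio",
    "subset_category_tests",
]


def load_disease_table(path: str | Path, source: str | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_id", "disease_id") if c not in table.columns]
    check(not missing, f"disease table {path}: missing columns {missing}")
    if source is not None and "source" in table.columns:
        table = table[table["source"] == source]
    return table.reset_index(drop=True)


def disease_fraction(gene_set: Iterable[str], disease_table: pd.DataFrame) -> float:
    """Fraction of set genes with at least one disease association; genes
    absent from the table count as unassociated."""
    genes = set(gene_set)
    check(bool(genes), "gene_set: empty set")
    associated = set(disease_table["gene_id"])
    return len(genes & associated) / len(genes)


def disease_resampling(
    gene_set: Iterable[str],
    background_genes: Iterable[str],
    disease_table: pd.DataFrame,
    n_samples: int = 100,
    seed: int | None = None,
) -> ResamplingResult:
    """Observed disease fraction vs ``n_samples`` random same-size samples
    drawn without replacement from the background."""
    genes = sorted(set(gene_set))
    background = sorted(set(background_genes))
    observed = disease_fraction(genes, disease_table)
    associated = set(disease_table["gene_id"])

    def statistic(sample):
        return sum(1 for g in sample if g in associated) / len(sample)

    return resampled_null(
        background, len(genes), statistic, observed,
        n_samples=n_samples, seed=seed,
    )


def enrichment_ratio(
    gene_set: Iterable[str],
    background_genes: Iterable[str],
    disease_table: pd.DataFrame,
) -> float:
    """Observed set fraction over the background fraction (the paper-style
    'n-fold higher than the proteome' ratio)."""
    bg_fraction = disease_fraction(background_genes, disease_table)
    if bg_fraction == 0:
        return float("nan")
    return disease_fraction(gene_set, disease_table) / bg_fraction


def subset_category_tests(
    gene_set: Iterable[str],
    background_genes: Iterable[str],
    disease_table: pd.DataFrame,
    category: str,
    n_samples: int = 100,
    seed: int | None = None,
) -> dict:
    """Association with one disease category (free-text ``category`` column):
    reports the set fraction, a Fisher exact p against the background, and
    the empirical resampling p."""
    check("category" in disease_table.columns,
          "disease_table: no 'category' column for a subset test")
    sub = disease_table[disease_table["category"] == category]
    genes = set(gene_set)
    background = set(background_genes)
    linked = set(sub["gene_id"])
    a = len(genes & linked)
    c = len((background - genes) & linked)
    table = [[a, len(genes) - a], [c, len(background - genes) - c]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    resampling = disease_resampling(genes, background, sub,
                                    n_samples=n_samples, seed=seed)
    return {
        "category": category,
        "set_count": a,
        "set_fraction": a / len(genes),
        "fisher_p": float(fisher_p),
        "empirical_p": resampling.empirical_p,
        "resampling": resampling,
    }
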