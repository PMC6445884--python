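"""Ordinal tissue-expression coding, set profiles, deviation vectors and
k-means clustering with silhouette-based selection of k.

Expression tables are gene x tissue matrices of ranks in {0, 1, 2, 3}
(none/low/medium/high); missing cells stay NaN and are excluded pairwise
from every mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._validation import ValidationError, check

logger = logging.getLogger(__name__)

__all__ = [
    "RANK_CODES",
    "ClusterResult",
    "code_expression",
    "load_expression",
    "set_tissue_profile",
    "deviation_vectors",
    "cluster_genes",
]

RANK_CODES = {"none": 0, "not detected": 0, "low": 1, "medium": 2, "high": 3}


def code_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert textual ranks (none/low/medium/high, case-insensitive) to
    0-3; numeric 0-3 values pass through; anything else becomes NaN with a
    warning."""
    def _code(value):
        if pd.isna(value):
            return np.nan
        if isinstance(value, str):
            key = value.strip().lower()
            if key in RANK_CODES:
                return float(RANK_CODES[key])
            try:
                value = float(key)
            except ValueError:
                return np.nan
        value = float(value)
        return value if value in (0.0, 1.0, 2.0, 3.0) else np.nan

    coded = raw.map(_code)
    n_missing = int(coded.isna().sum().sum()) - int(raw.isna().sum().sum())
    if n_missing > 0:
        logger.warning("code_expression: %d unrecognized labels flagged missing",
                       n_missing)
    return coded


def load_expression(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0)
    return code_expression(raw)


def set_tissue_profile(
    set_genes: Iterable[str],
    table: pd.DataFrame,
    cell_type_map: dict[str, str] | None = None,
) -> pd.Series:
    """Per-tissue mean expression over the set genes (missing cells excluded).

    If ``cell_type_map`` maps column labels to tissue names, cell-type
    columns are averaged into tissues before averaging over genes.
    """
    if cell_type_map:
        table = table.T.groupby(
            lambda col: cell_type_map.get(col, col)
        ).mean().T
    present = [g for g in set_genes if g in table.index]
    if not present:
        raise ValidationError("set_genes: no overlap with the expression table")
    return table.loc[present].mean(axis=0, skipna=True)


def deviation_vectors(
    set_genes: Iterable[str],
    set_table: pd.DataFrame,
    background_table: pd.DataFrame,
) -> pd.DataFrame:
    """V_g[t] = E_g,t - mean over background genes of E_.,t.

    Background means use all background genes with a non-missing value in
    the tissue.  Tissue columns of the two tables must match exactly.
    """
    if list(set_table.columns) != list(background_table.columns):
        raise ValidationError(
            "background_table: tissue columns do not align with set_table"
        )
    present = [g for g in set_genes if g in set_table.index]
    if not present:
        raise ValidationError("set_genes: no overlap with the expression table")
    background_mean = background_table.mean(axis=0, skipna=True)
    return set_table.loc[present].sub(background_mean, axis=1)


@dataclass
class ClusterResult:
    chosen_k: int
    labels: dict[str, int]
    silhouette_by_k: dict[int, float]
    seed: int | None
    excluded_genes: list[str]


def cluster_genes(
    vectors: pd.DataFrame,
    k_min: int = 3,
    k_max: int = 10,
    n_restarts: int = 25,
    seed: int | None = None,
    max_missing_fraction: float = 0.5,
) -> ClusterResult:
    """k-means (Euclidean, k-means++ with ``n_restarts`` seeded inits) for
    each k in [k_min, k_max]; chosen_k maximizes mean silhouette, ties to
    the smaller k.

    Genes missing more than half their tissues are excluded (logged);
    remaining missing components are treated as zero deviation.
    """
    check(k_min >= 2, "k_min: must be >= 2")
    check(k_max >= k_min, "k_max: must be >= k_min")
    missing_frac = vectors.isna().mean(axis=1)
    excluded = list(vectors.index[missing_frac > max_missing_fraction])
    if excluded:
        logger.warning("cluster_genes: excluded %d genes with >%.0f%% missing: %s",
                       len(excluded), 100 * max_missing_fraction, excluded[:10])
    kept = vectors.drop(index=excluded)
    n = len(kept)
    if n < k_max + 1:
        new_max = max(k_min, n - 1)
        logger.warning("cluster_genes: only %d genes; truncating k range to %d..%d",
                       n, k_min, new_max)
        k_max = new_max
        check(n >= k_min + 1, "vectors: too few genes to cluster")
    X = kept.fillna(0.0).to_numpy(dtype=float)

    silhouettes: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        silhouettes[k] = float(silhouette_score(X, labels, metric="euclidean"))
        best_labels[k] = labels
    chosen_k = max(sorted(silhouettes), key=lambda k: (silhouettes[k], -k))
    return ClusterResult(
        chosen_k=chosen_k,
        labels=dict(zip(kept.index, best_labels[chosen_k].tolist())),
        silhouette_by_k=silhouettes,
        seed=seed,
        excluded_genes=excluded,
    )


def write_clusters_tsv(result: ClusterResult, path: str | Path) -> None:
    pd.DataFrame(
        sorted(result.labels.items()), columns=["gene_id", "cluster"]
    ).to_csv(path, sep="\t", index=False)


def write_silhouette_tsv(result: ClusterResult, path: str | Path) -> None:
    pd.DataFrame(
        sorted(result.silhouette_by_k.items()), columns=["k", "mean_silhouette"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
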