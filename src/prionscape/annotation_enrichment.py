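"""Term enrichment of a protein set against a background.

Evidence-code filtering and optional slim-term collapsing, then a two-sided
Fisher's exact test per term with Bonferroni correction over the terms
tested in the namespace, plus a log-ratio enrichment score
E = ln(term freq among set annotations) - ln(term freq among background
annotations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from ._validation import ValidationError, check

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "load_annotations",
    "filter_annotations",
    "fisher_test",
    "term_enrichment",
    "log_enrichment_score",
]


def fisher_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])

COLUMNS = ["protein_id", "term_id", "namespace", "evidence"]


@dataclass
class EnrichmentRow:
    term_id: str
    set_count: int
    set_total: int
    background_count: int
    background_total: int
    odds_ratio: float  # NaN for degenerate margins
    fisher_p: float
    adjusted_p: float
    direction: str  # enriched | depleted | none
    score_E: float  # NaN when the term is absent from the set


def load_annotations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLUMNS if c not in table.columns]
    check(not missing, f"annotations {path}: missing columns {missing}")
    return table.drop_duplicates(subset=["protein_id", "term_id"]).reset_index(
        drop=True
    )


def _resolve_slim(slim_map: dict[str, str]) -> dict[str, str]:
    """Follow term -> slim chains to their fixed point; cycles are an error."""
    resolved = {}
    for term in slim_map:
        seen = {term}
        current = term
        while current in slim_map and slim_map[current] != current:
            current = slim_map[current]
            if current in seen:
                raise ValidationError(f"slim_map: cycle involving {term}")
            seen.add(current)
        resolved[term] = current
    return resolved


def filter_annotations(
    table: pd.DataFrame,
    excluded_evidence: Iterable[str] = ("IEA",),
    slim_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Drop rows with excluded evidence codes; optionally map terms onto
    their slim targets and collapse duplicates."""
    excluded = set(excluded_evidence)
    out = table[~table["evidence"].isin(excluded)].copy()
    if out.empty and not table.empty:
        logger.warning("filter_annotations: all %d rows removed by evidence filter",
                       len(table))
    if slim_map:
        resolved = _resolve_slim(slim_map)
        out["term_id"] = out["term_id"].map(lambda t: resolved.get(t, t))
    return out.drop_duplicates(subset=["protein_id", "term_id"]).reset_index(
        drop=True
    )


def _direction(a: int, set_total: int, bg_count: int, bg_total: int) -> str:
    set_freq = a / set_total if set_total else 0.0
    bg_freq = bg_count / bg_total if bg_total else 0.0
    if set_freq > bg_freq:
        return "enriched"
    if set_freq < bg_freq:
        return "depleted"
    return "none"


def term_enrichment(
    set_ids: Iterable[str],
    background_ids: Iterable[str],
    table: pd.DataFrame,
    namespace: str | None = None,
) -> list[EnrichmentRow]:
    """Two-sided Fisher tests of every term annotated in the background,
    Bonferroni-corrected over the family of terms tested, sorted by
    adjusted p (ties by raw p, then term id).

    The 2x2 table per term is (in-set with term, in-set without, out-of-set
    with term, out-of-set without), where out-of-set means background
    proteins not in the set.
    """
    set_ids = set(set_ids)
    background_ids = set(background_ids)
    check(bool(set_ids), "set_ids: empty set")
    if not set_ids <= background_ids:
        raise ValidationError("set_ids: set must be a subset of background_ids")
    sub = table[table["protein_id"].isin(background_ids)]
    if namespace is not None:
        sub = sub[sub["namespace"] == namespace]
    sub = sub.drop_duplicates(subset=["protein_id", "term_id"])
    set_total = len(set_ids)
    out_total = len(background_ids) - set_total
    # per-annotation totals for the E score
    ann_set_total = int(sub["protein_id"].isin(set_ids).sum())
    ann_bg_total = len(sub)

    rows = []
    grouped = sub.groupby("term_id")["protein_id"]
    m = grouped.ngroups
    for term_id, proteins in grouped:
        members = set(proteins)
        a = len(members & set_ids)
        b = set_total - a
        c = len(members) - a
        d = out_total - c
        p = fisher_test(a, b, c, d)
        odds = (a * d) / (b * c) if b * c > 0 else float("nan")
        if ann_set_total > 0 and a > 0:
            score_e = math.log((a / ann_set_total) / (len(members) / ann_bg_total))
        else:
            score_e = float("nan")
        rows.append(EnrichmentRow(
            term_id=term_id,
            set_count=a,
            set_total=set_total,
            background_count=len(members),
            background_total=len(background_ids),
            odds_ratio=float(odds),
            fisher_p=float(p),
            adjusted_p=min(1.0, m * float(p)),
            direction=_direction(a, set_total, len(members), len(background_ids)),
            score_E=score_e,
        ))
    rows.sort(key=lambda r: (r.adjusted_p, r.fisher_p, r.term_id))
    return rows


def log_enrichment_score(
    term: str,
    set_ids: Iterable[str],
    background_ids: Iterable[str],
    table: pd.DataFrame,
    per_protein: bool = False,
) -> float:
    """E = ln(term frequency in the set) - ln(term frequency in background).

    Frequencies are per annotation row by default (term occurrences over
    total annotations of the group); ``per_protein=True`` switches the
    denominators to protein counts.  Returns NaN when the term is absent
    from the set; a term absent from the background is an error.
    """
    set_ids = set(set_ids)
    background_ids = set(background_ids)
    sub = table[table["protein_id"].isin(background_ids)].drop_duplicates(
        subset=["protein_id", "term_id"]
    )
    in_set = sub[sub["protein_id"].isin(set_ids)]
    bg_count = int((sub["term_id"] == term).sum())
    if bg_count == 0:
        raise ValidationError(f"term: {term} not annotated in the background")
    set_count = int((in_set["term_id"] == term).sum())
    if set_count == 0:
        return float("nan")
    if per_protein:
        set_total, bg_total = len(set_ids), len(background_ids)
    else:
        set_total, bg_total = len(in_set), len(sub)
    return math.log(set_count / set_total) - math.log(bg_count / bg_total)


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    enrichment_to_frame(rows).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")
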