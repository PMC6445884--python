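"""Terminal localization of called domains under a 25/50/25 segmentation.

Each protein is split into an N-terminal quarter, an internal half and a
C-terminal quarter (sizes rounded half-even, C segment sized first); a call
is assigned to the segment holding the plurality of its residues, ties going
to internal.  The C-vs-N imbalance is tested with a one-sample proportion
Z-test against 0.5.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from ._validation import ValidationError, check
from .prld_detection import PrLDCall

__all__ = [
    "SegmentScheme",
    "LocalizationEntry",
    "LocalizationResult",
    "segment_boundaries",
    "classify_prld",
    "classify_interval",
    "terminal_bias_test",
    "position_histogram",
    "localize_calls",
]


@dataclass(frozen=True)
class SegmentScheme:
    n_fraction: float = 0.25
    c_fraction: float = 0.25

    def __post_init__(self):
        check(0 < self.n_fraction and 0 < self.c_fraction,
              "n_fraction/c_fraction: must be positive")
        check(self.n_fraction + self.c_fraction < 1,
              "n_fraction + c_fraction must be < 1")


@dataclass
class LocalizationEntry:
    protein_id: str
    n_count: int
    internal_count: int
    c_count: int
    category: str  # N | internal | C


@dataclass
class LocalizationResult:
    entries: list[LocalizationEntry]
    n_terminal: int
    internal: int
    c_terminal: int
    z_statistic: float
    p_value: float
    c_to_n_ratio: float  # NaN when no N-terminal calls


def _round_half_even(x: float) -> int:
    # Python's round() is banker's rounding
    return int(round(x))


def segment_boundaries(
    protein_length: int, scheme: SegmentScheme = SegmentScheme()
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """1-based inclusive (N, internal, C) intervals exactly partitioning 1..L.

    Segment sizes are rounded half-even, C sized first; the internal segment
    absorbs the remainder.
    """
    if protein_length < 4:
        raise ValidationError(
            f"protein_length: {protein_length} < 4, cannot segment"
        )
    L = protein_length
    c_size = _round_half_even(0.25 * L)
    n_size = _round_half_even(0.25 * L)
    if n_size + c_size >= L:  # degenerate tiny lengths
        c_size = max(1, L // 4)
        n_size = max(1, L // 4)
    return (
        (1, n_size),
        (n_size + 1, L - c_size),
        (L - c_size + 1, L),
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_interval(
    start: int, end: int, protein_length: int,
    scheme: SegmentScheme = SegmentScheme(),
    rule: str = "plurality",
) -> tuple[int, int, int, str]:
    """Segment residue counts and category for a 1-based inclusive interval.

    ``rule`` selects the assignment convention: ``plurality`` (ties ->
    internal, the pinned default), ``midpoint`` (segment containing the
    interval midpoint) or ``any_overlap`` (N if the interval touches the N
    quarter, else C if it touches the C quarter, else internal).
    """
    if not (1 <= start <= end <= protein_length):
        raise ValidationError(
            f"interval: {start}..{end} out of range for length {protein_length}"
        )
    n_seg, i_seg, c_seg = segment_boundaries(protein_length, scheme)
    dom = (start, end)
    counts = (_overlap(dom, n_seg), _overlap(dom, i_seg), _overlap(dom, c_seg))
    if rule == "plurality":
        best = max(counts)
        winners = [i for i, c in enumerate(counts) if c == best]
        category = ("N", "internal", "C")[winners[0]] if len(winners) == 1 else "internal"
    elif rule == "midpoint":
        mid = (start + end) // 2
        if mid <= n_seg[1]:
            category = "N"
        elif mid >= c_seg[0]:
            category = "C"
        else:
            category = "internal"
    elif rule == "any_overlap":
        if counts[0] > 0:
            category = "N"
        elif counts[2] > 0:
            category = "C"
        else:
            category = "internal"
    else:
        raise ValidationError(f"rule: unknown assignment rule {rule!r}")
    return counts[0], counts[1], counts[2], category


def classify_prld(
    call: PrLDCall, protein_length: int,
    scheme: SegmentScheme = SegmentScheme(),
    rule: str = "plurality",
) -> LocalizationEntry:
    check(call.domain_start is not None and call.domain_end is not None,
          "call: cannot localize a no-call (missing domain interval)")
    n, i, c, category = classify_interval(
        call.domain_start, call.domain_end, protein_length, scheme, rule
    )
    return LocalizationEntry(call.protein_id, n, i, c, category)


def terminal_bias_test(n_count_n: int, n_count_c: int) -> tuple[float, float, float]:
    """One-sample proportion Z-test of the C share against 0.5 over terminal
    calls; returns (z, two-sided p, C/N ratio).  Ratio is NaN when no
    N-terminal calls exist."""
    check(n_count_n >= 0 and n_count_c >= 0, "counts: must be non-negative")
    n = n_count_n + n_count_c
    if n < 1:
        raise ValidationError("counts: need at least one terminal call")
    z = (n_count_c - n / 2.0) / np.sqrt(n / 4.0)
    p = 2.0 * stats.norm.sf(abs(z))
    ratio = n_count_c / n_count_n if n_count_n > 0 else float("nan")
    return float(z), float(min(1.0, p)), float(ratio)


def position_histogram(
    calls: Sequence[PrLDCall],
    protein_lengths: dict[str, int],
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Start-position and end-position bin counts over relative sequence
    position: bin(pos) = floor((pos - 1) / L * n_bins), clamped to the last bin."""
    check(n_bins >= 1, "n_bins: must be >= 1")
    starts = np.zeros(n_bins, dtype=int)
    ends = np.zeros(n_bins, dtype=int)
    for call in calls:
        if call.domain_start is None:
            continue
        L = protein_lengths[call.protein_id]
        for pos, vec in ((call.domain_start, starts), (call.domain_end, ends)):
            b = min(n_bins - 1, int((pos - 1) / L * n_bins))
            vec[b] += 1
    return starts, ends


def localize_calls(
    calls: Sequence[PrLDCall],
    protein_lengths: dict[str, int],
    scheme: SegmentScheme = SegmentScheme(),
    rule: str = "plurality",
    positives_only: bool = True,
) -> LocalizationResult:
    """Classify every (positive) call and run the terminal imbalance test."""
    entries = []
    for call in calls:
        if positives_only and not call.positive:
            continue
        if call.domain_start is None:
            continue
        entries.append(classify_prld(call, protein_lengths[call.protein_id],
                                     scheme, rule))
    tallies = {"N": 0, "internal": 0, "C": 0}
    for e in entries:
        tallies[e.category] += 1
    if tallies["N"] + tallies["C"] >= 1:
        z, p, ratio = terminal_bias_test(tallies["N"], tallies["C"])
    else:
        z, p, ratio = float("nan"), float("nan"), float("nan")
    return LocalizationResult(
        entries=entries,
        n_terminal=tallies["N"],
        internal=tallies["internal"],
        c_terminal=tallies["C"],
        z_statistic=z,
        p_value=p,
        c_to_n_ratio=ratio,
    )


def write_localization_tsv(result: LocalizationResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "n_count", "internal_count", "c_count",
                         "category"])
        for e in result.entries:
            writer.writerow([e.protein_id, e.n_count, e.internal_count,
                             e.c_count, e.category])


def write_localization_summary(result: LocalizationResult, path: str | Path) -> None:
    payload = {
        "n_terminal": result.n_terminal,
        "internal": result.internal,
        "c_terminal": result.c_terminal,
        "z_statistic": result.z_statistic,
        "p_value": result.p_value,
        "c_to_n_ratio": result.c_to_n_ratio,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
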