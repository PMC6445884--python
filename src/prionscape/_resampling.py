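"""Empirical resampling nulls shared by the disease and network stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._validation import ValidationError, check

__all__ = ["ResamplingResult", "nearest_rank_percentile", "resampled_null"]


@dataclass
class ResamplingResult:
    """Observed statistic against an empirical null of random same-size sets.

    ``z`` is NaN when the null is degenerate (sd == 0).  ``empirical_p`` uses
    the (r + 1) / (n + 1) estimator with r = #{null >= observed}, so it is
    never 0.  ``percentile_rank`` is the fraction of null samples strictly
    below the observed value.  ``above_95th`` flags observed values strictly
    above the nearest-rank 95th percentile of the null.
    """

    observed: float
    null_samples: np.ndarray
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    percentile_rank: float
    above_95th: bool
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "empirical_p": self.empirical_p,
            "percentile_rank": self.percentile_rank,
            "above_95th": bool(self.above_95th),
            "n_excluded": self.n_excluded,
            "null_samples": [float(x) for x in self.null_samples],
        }


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: smallest value with at least q% of mass below-or-at."""
    arr = np.sort(np.asarray(values, dtype=float))
    check(arr.size > 0, "values: need at least one sample for a percentile")
    rank = max(1, math.ceil(q / 100.0 * arr.size))
    return float(arr[rank - 1])


def summarize_null(
    observed: float, null_samples: np.ndarray, n_excluded: int = 0
) -> ResamplingResult:
    null = np.asarray(null_samples, dtype=float)
    check(null.size >= 1, "null_samples: empty null distribution")
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    r = int(np.sum(null >= observed))
    empirical_p = (1 + r) / (null.size + 1)
    percentile_rank = float(np.mean(null < observed))
    above = observed > nearest_rank_percentile(null, 95.0)
    return ResamplingResult(
        observed=float(observed),
        null_samples=null,
        null_mean=mean,
        null_sd=sd,
        z=z,
        empirical_p=empirical_p,
        percentile_rank=percentile_rank,
        above_95th=above,
        n_excluded=n_excluded,
    )


def resampled_null(
    background: Sequence,
    set_size: int,
    statistic: Callable[[Sequence], float],
    observed: float,
    n_samples: int = 100,
    seed: int | np.random.Generator | None = None,
) -> ResamplingResult:
    """Draw ``n_samples`` random subsets (without replacement) of
    ``set_size`` items from ``background``, evaluate ``statistic`` on each,
    and summarize ``observed`` against the resulting null.

    Draws that evaluate to NaN (e.g. undefined mean shortest distance) are
    excluded from the null and counted in ``n_excluded``.
    """
    background = list(background)
    check(n_samples >= 1, "n_samples: must be >= 1")
    if set_size > len(background):
        raise ValidationError(
            f"set_size: {set_size} exceeds background size {len(background)}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    items = np.asarray(background, dtype=object)
    samples = []
    n_excluded = 0
    for _ in range(n_samples):
        draw = rng.choice(items, size=set_size, replace=False)
        value = float(statistic(list(draw)))
        if math.isnan(value):
            n_excluded += 1
        else:
            samples.append(value)
    if not samples:
        raise ValidationError(
            "statistic: every null draw was undefined (all-NaN null)"
        )
    return summarize_null(observed, np.asarray(samples), n_excluded=n_excluded)
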