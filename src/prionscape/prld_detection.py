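"""Two-stage prion-like domain caller.

Stage 1 scans each sequence with a per-residue compositional log-likelihood
ratio (prion-domain vs background amino-acid frequencies), calls the
maximal-sum window of ``core_length`` residues, and greedily extends it into
the reported domain.  Stage 2 scores every 21-mer inside the domain with a
position-weight matrix, rescales the best raw sum to 0-100, and accepts the
call when that score reaches the cutoff (default 60.00).

Coordinates are 0-based half-open internally; :class:`PrLDCall` and all
serialized output use 1-based inclusive positions.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._validation import ValidationError, check

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_CUTOFF = 60.00
CORE_WINDOW = 21  # amyloid-core window length (residues)

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_CUTOFF",
    "CompositionModel",
    "AmyloidMatrix",
    "PrLDCall",
    "estimate_background_frequencies",
    "llr_profile",
    "find_prion_domain",
    "amyloid_core_score",
    "call_prionlike",
    "read_fasta",
    "write_calls_tsv",
    "write_calls_json",
]


def normalize_frequencies(freqs: dict[str, float], floor: float = 1e-6) -> dict[str, float]:
    """Floor every standard residue at ``floor`` and renormalize to sum 1."""
    floored = {aa: max(float(freqs.get(aa, 0.0)), floor) for aa in AMINO_ACIDS}
    total = sum(floored.values())
    return {aa: v / total for aa, v in floored.items()}


def _read_freq_tsv(handle) -> dict[str, float]:
    freqs = {}
    for row in csv.DictReader(handle, delimiter="\t"):
        freqs[row["aa"]] = float(row["freq"])
    return freqs


@dataclass(frozen=True)
class CompositionModel:
    """Prion-domain and background amino-acid frequencies plus core length."""

    prion_freqs: dict[str, float]
    background_freqs: dict[str, float]
    core_length: int = 60

    def __post_init__(self):
        check(self.core_length >= 1, "core_length: must be >= 1")
        for name, table in (
            ("prion_freqs", self.prion_freqs),
            ("background_freqs", self.background_freqs),
        ):
            check(
                abs(sum(table.values()) - 1.0) <= 1e-9,
                f"{name}: frequencies must sum to 1",
            )
            check(
                all(table.get(aa, 0.0) > 0 for aa in AMINO_ACIDS),
                f"{name}: all 20 standard residues need probability > 0",
            )

    @classmethod
    def default(cls, background_freqs: dict[str, float] | None = None,
                core_length: int = 60) -> "CompositionModel":
        """Shipped prion-domain composition; background from package data
        unless an estimate (e.g. from the scanned proteome) is supplied."""
        with resources.files("prionscape.data").joinpath("prion_freqs.tsv").open() as fh:
            prion = normalize_frequencies(_read_freq_tsv(fh))
        if background_freqs is None:
            with resources.files("prionscape.data").joinpath(
                "background_freqs.tsv"
            ).open() as fh:
                background_freqs = _read_freq_tsv(fh)
        return cls(
            prion_freqs=prion,
            background_freqs=normalize_frequencies(background_freqs),
            core_length=core_length,
        )

    @classmethod
    def from_tsv(cls, prion_path: str | Path,
                 background_path: str | Path | None = None,
                 core_length: int = 60) -> "CompositionModel":
        with open(prion_path) as fh:
            prion = normalize_frequencies(_read_freq_tsv(fh))
        if background_path is not None:
            with open(background_path) as fh:
                background = normalize_frequencies(_read_freq_tsv(fh))
        else:
            background = cls.default().background_freqs
        return cls(prion_freqs=prion, background_freqs=background,
                   core_length=core_length)


@dataclass(frozen=True)
class AmyloidMatrix:
    """21-position x 20-residue weight matrix with a fixed 0-100 rescaling.

    ``score_min`` / ``score_max`` are the theoretical minimum and maximum
    21-mer raw sums of the matrix, pinning the linear rescale used for the
    cutoff (default 60.00).
    """

    weights: np.ndarray  # shape (21, 20), row = position, col = AMINO_ACIDS order
    score_min: float
    score_max: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        check(self.weights.shape == (CORE_WINDOW, 20),
              "weights: expected a 21-position x 20-residue matrix")
        check(self.score_max > self.score_min,
              "score_max: must exceed score_min")

    @classmethod
    def from_weights(cls, weights: np.ndarray, cutoff: float = DEFAULT_CUTOFF
                     ) -> "AmyloidMatrix":
        weights = np.asarray(weights, dtype=float)
        return cls(
            weights=weights,
            score_min=float(weights.min(axis=1).sum()),
            score_max=float(weights.max(axis=1).sum()),
            cutoff=cutoff,
        )

    @classmethod
    def default(cls, cutoff: float = DEFAULT_CUTOFF) -> "AmyloidMatrix":
        with resources.files("prionscape.data").joinpath(
            "amyloid_matrix.tsv"
        ).open() as fh:
            return cls._parse(fh, cutoff)

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = DEFAULT_CUTOFF
                 ) -> "AmyloidMatrix":
        with open(path) as fh:
            return cls._parse(fh, cutoff)

    @classmethod
    def _parse(cls, handle, cutoff: float) -> "AmyloidMatrix":
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        cols = header[1:]
        check(sorted(cols) == sorted(AMINO_ACIDS),
              "amyloid matrix: header must list the 20 standard residues")
        order = [cols.index(aa) for aa in AMINO_ACIDS]
        rows = []
        for row in reader:
            values = [float(x) for x in row[1:]]
            rows.append([values[i] for i in order])
        return cls.from_weights(np.asarray(rows), cutoff=cutoff)

    def rescale(self, raw: float) -> float:
        """Linear raw-sum -> 0-100 score, clamped."""
        score = (raw - self.score_min) / (self.score_max - self.score_min) * 100.0
        return float(min(100.0, max(0.0, score)))


@dataclass
class PrLDCall:
    """One prion-like domain call (1-based inclusive coordinates)."""

    protein_id: str
    domain_start: int | None
    domain_end: int | None
    core_score: float | None
    amyloid_core_start: int | None
    amyloid_core_end: int | None
    amyloid_score: float | None
    passes_composition: bool
    passes_amyloid: bool

    @property
    def positive(self) -> bool:
        return self.passes_composition and self.passes_amyloid


def estimate_background_frequencies(
    sequences: Iterable[str], floor: float = 1e-6
) -> dict[str, float]:
    """Pooled amino-acid frequencies of a proteome (non-standard residues
    skipped with a logged count), pseudocount-floored and renormalized."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    skipped = 0
    total = 0
    n_seqs = 0
    for seq in sequences:
        n_seqs += 1
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
                total += 1
            else:
                skipped += 1
    check(n_seqs > 0 and total > 0, "proteome: empty proteome")
    if skipped:
        logger.info("estimate_background_frequencies: skipped %d non-standard residues", skipped)
    return normalize_frequencies(
        {aa: c / total for aa, c in counts.items()}, floor=floor
    )


def llr_profile(sequence: str, model: CompositionModel) -> np.ndarray:
    """Per-residue log(prion/background) score vector; unknown residues score 0."""
    check(len(sequence) >= 1, "sequence: must have length >= 1")
    table = np.zeros(26)
    for aa in AMINO_ACIDS:
        table[ord(aa) - 65] = np.log(
            model.prion_freqs[aa] / model.background_freqs[aa]
        )
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).astype(int) - 65
    unknown = (codes < 0) | (codes > 25)
    if unknown.any():
        logger.info("llr_profile: %d unknown residues scored 0", int(unknown.sum()))
    codes = np.clip(codes, 0, 25)
    profile = table[codes]
    profile[unknown] = 0.0
    # non-standard letters inside A-Z (B, J, O, U, X, Z) also score 0
    nonstd = np.isin(codes, [ord(c) - 65 for c in "BJOUXZ"])
    profile[nonstd] = 0.0
    return profile


def find_prion_domain(
    profile: np.ndarray, model: CompositionModel
) -> tuple[tuple[int, int], float] | None:
    """Best fixed-length core window plus greedy positive-sum extension.

    Returns ``((start, end), core_score)`` with a 0-based half-open domain
    interval, or None when the sequence is shorter than ``core_length`` or no
    window has a positive sum.  Ties break leftmost.
    """
    profile = np.asarray(profile, dtype=float)
    L = model.core_length
    n = profile.size
    if n < L:
        return None
    csum = np.concatenate([[0.0], np.cumsum(profile)])
    window_sums = csum[L:] - csum[:-L]
    best = int(np.argmax(window_sums))  # argmax returns the leftmost maximum
    core_score = float(window_sums[best])
    if core_score <= 0:
        return None
    start, end = best, best + L
    # greedy extension: walk outward while the running extension sum stays positive
    run = 0.0
    for i in range(end, n):
        run += profile[i]
        if run <= 0:
            break
        end = i + 1
    run = 0.0
    for i in range(start - 1, -1, -1):
        run += profile[i]
        if run <= 0:
            break
        start = i
    return (start, end), core_score


def amyloid_core_score(
    domain_sequence: str, matrix: AmyloidMatrix
) -> tuple[tuple[int, int], float] | None:
    """Best 21-mer interval (0-based half-open, relative to the domain) and
    its 0-100 score.  Windows containing non-standard residues are excluded;
    None when the domain is shorter than 21 or no window is scoreable."""
    seq = domain_sequence.upper()
    n = len(seq)
    if n < CORE_WINDOW:
        return None
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(idx, CORE_WINDOW)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return None
    pos = np.arange(CORE_WINDOW)
    raw = np.where(
        valid,
        matrix.weights[pos, np.clip(windows, 0, 19)].sum(axis=1),
        -np.inf,
    )
    best = int(np.argmax(raw))
    return (best, best + CORE_WINDOW), matrix.rescale(float(raw[best]))


def call_prionlike(
    records: Sequence[tuple[str, str]] | dict[str, str],
    model: CompositionModel | None = None,
    matrix: AmyloidMatrix | None = None,
    cutoff: float | None = None,
) -> list[PrLDCall]:
    """Run both stages over ``records`` ((protein_id, sequence) pairs or an
    id->sequence mapping); returns calls sorted by protein id.

    Stage 2 runs only on stage-1 passers; a call is positive when it passes
    composition and its amyloid score reaches the cutoff.
    """
    if isinstance(records, dict):
        records = list(records.items())
    model = model or CompositionModel.default()
    matrix = matrix or AmyloidMatrix.default()
    if cutoff is None:
        cutoff = matrix.cutoff
    calls = []
    for protein_id, seq in sorted(records, key=lambda r: r[0]):
        domain = None
        if len(seq) >= 1:
            domain = find_prion_domain(llr_profile(seq, model), model)
        if domain is None:
            calls.append(PrLDCall(protein_id, None, None, None, None, None,
                                  None, False, False))
            continue
        (dstart, dend), core_score = domain
        amyloid = amyloid_core_score(seq[dstart:dend], matrix)
        if amyloid is None:
            calls.append(PrLDCall(protein_id, dstart + 1, dend, core_score,
                                  None, None, None, True, False))
            continue
        (astart, aend), ascore = amyloid
        calls.append(PrLDCall(
            protein_id,
            dstart + 1, dend, core_score,
            dstart + astart + 1, dstart + aend, ascore,
            True, ascore >= cutoff,
        ))
    return calls


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a proteome FASTA; headers ``>protein_id|gene_id`` or ``>protein_id``.

    Returns (protein_id, gene_id, sequence) triples (gene_id falls back to the
    protein id when absent).
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:  # pragma: no cover - passthrough context
        raise ValidationError(f"FASTA {path}: {exc}") from exc
    check(bool(records), f"FASTA {path}: no records")
    out = []
    for rec in records:
        parts = rec.id.split("|")
        protein_id = parts[0]
        gene_id = parts[1] if len(parts) > 1 and parts[1] else protein_id
        out.append((protein_id, gene_id, str(rec.seq).upper()))
    return out


_TSV_COLUMNS = [
    "protein_id", "domain_start", "domain_end", "core_score",
    "amyloid_start", "amyloid_end", "amyloid_score", "positive",
]


def write_calls_tsv(calls: Sequence[PrLDCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for c in calls:
            writer.writerow([
                c.protein_id,
                c.domain_start if c.domain_start is not None else "NA",
                c.domain_end if c.domain_end is not None else "NA",
                f"{c.core_score:.4f}" if c.core_score is not None else "NA",
                c.amyloid_core_start if c.amyloid_core_start is not None else "NA",
                c.amyloid_core_end if c.amyloid_core_end is not None else "NA",
                f"{c.amyloid_score:.4f}" if c.amyloid_score is not None else "NA",
                int(c.positive),
            ])


def read_calls_tsv(path: str | Path) -> list[PrLDCall]:
    calls = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            def _num(key, cast):
                return None if row[key] == "NA" else cast(row[key])
            calls.append(PrLDCall(
                protein_id=row["protein_id"],
                domain_start=_num("domain_start", int),
                domain_end=_num("domain_end", int),
                core_score=_num("core_score", float),
                amyloid_core_start=_num("amyloid_start", int),
                amyloid_core_end=_num("amyloid_end", int),
                amyloid_score=_num("amyloid_score", float),
                passes_composition=row["domain_start"] != "NA",
                passes_amyloid=bool(int(row["positive"])),
            ))
    return calls


def write_calls_json(calls: Sequence[PrLDCall], path: str | Path) -> None:
    payload = [
        {
            "protein_id": c.protein_id,
            "domain_start": c.domain_start,
            "domain_end": c.domain_end,
            "core_score": c.core_score,
            "amyloid_core_start": c.amyloid_core_start,
            "amyloid_core_end": c.amyloid_core_end,
            "amyloid_score": c.amyloid_score,
            "passes_composition": c.passes_composition,
            "passes_amyloid": c.passes_amyloid,
            "positive": c.positive,
        }
        for c in calls
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
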