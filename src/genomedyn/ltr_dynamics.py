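"""LTR retrotransposon insertion dating, solo-LTR screening and summaries.

A full-length LTR-RT carries two terminal repeats that were identical at
insertion; their divergence K (Jukes-Cantor corrected) dates the insertion
as T = K / (2 r), with r the neutral substitution rate per site per year
(default 1.33e-9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import needleman_wunsch
from .errors import EstimationError, SaturationError, ValidationError
from .io_formats import LtrElementRow, SequenceRecord

__all__ = [
    "DEFAULT_RATE",
    "LtrDivergence",
    "RateCurve",
    "SuperfamilyMass",
    "align_ltr_pair",
    "ltr_divergence",
    "date_elements",
    "classify_solo_ltrs",
    "solo_paired_ratio",
    "transposition_rate_curve",
    "superfamily_masses",
]

#: neutral substitution rate, substitutions / site / year
DEFAULT_RATE = 1.33e-9


@dataclass(frozen=True)
class LtrDivergence:
    """Divergence and insertion date for one full-length element."""

    element_id: str
    aligned_sites: int   # gap- and N-free columns
    mismatches: int
    p_distance: float
    K: float             # JC-corrected substitutions per site
    T: float             # insertion time, years


@dataclass
class RateCurve:
    """Insertions per time bin plus the past-directed accumulation curve."""

    bin_width: float                 # years
    horizon: float                   # years
    counts: np.ndarray               # insertions per [i*w, (i+1)*w)
    accumulation: np.ndarray         # cumulative counts from present backwards
    n_excluded: int                  # elements with T >= horizon

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SuperfamilyMass:
    superfamily: str
    total_bp: float
    fraction_of_genome: float   # percent, 2 decimals
    n_elements: int = 0


def align_ltr_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Globally align the two terminal repeats of one element."""
    if not seq5 or not seq3:
        raise ValidationError("cannot align an empty LTR sequence")
    aln5, aln3, _ = needleman_wunsch(seq5.upper(), seq3.upper())
    return aln5, aln3


def _pair_counts(aln5: str, aln3: str) -> tuple[int, int]:
    """Aligned (gap- and N-free) columns and mismatches among them."""
    sites = mismatches = 0
    for x, y in zip(aln5, aln3):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x != y:
            mismatches += 1
    return sites, mismatches


def ltr_divergence(
    alignment: tuple[str, str],
    r: float = DEFAULT_RATE,
    element_id: str = "",
    correction: str = "jc",
) -> LtrDivergence:
    """Convert an aligned LTR pair into K and an insertion time T = K/(2r).

    Gap and N columns are excluded from both numerator and denominator.
    ``correction="jc"`` applies K = -(3/4) ln(1 - (4/3) p); ``"raw"`` reports
    K = p. A p-distance at or beyond 0.75 raises :class:`SaturationError`
    (the element is undatable).
    """
    if correction not in ("jc", "raw"):
        raise ValidationError(f"unknown correction {correction!r}")
    aln5, aln3 = alignment
    sites, mismatches = _pair_counts(aln5, aln3)
    if sites == 0:
        raise EstimationError(f"element {element_id!r}: no aligned sites")
    p = mismatches / sites
    if correction == "jc":
        if p >= 0.75:
            raise SaturationError(
                f"element {element_id!r}: p-distance {p:.3f} >= 0.75, undatable"
            )
        K = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    else:
        K = p
    return LtrDivergence(
        element_id=element_id,
        aligned_sites=sites,
        mismatches=mismatches,
        p_distance=p,
        K=K,
        T=K / (2.0 * r),
    )


def date_elements(
    genome: Mapping[str, str] | Sequence[SequenceRecord],
    elements: Sequence[LtrElementRow],
    r: float = DEFAULT_RATE,
    correction: str = "jc",
) -> tuple[list[LtrDivergence], list[str]]:
    """Date every full-length element; returns (dated, undatable element ids)."""
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec.sequence for rec in genome}
    dated: list[LtrDivergence] = []
    undatable: list[str] = []
    for el in elements:
        try:
            chrom_seq = genome[el.chrom]
        except KeyError:
            raise ValidationError(
                f"element {el.element_id!r} on unknown sequence {el.chrom!r}"
            ) from None
        seq5 = chrom_seq[el.ltr5_start : el.ltr5_end]
        seq3 = chrom_seq[el.ltr3_start : el.ltr3_end]
        aln = align_ltr_pair(seq5, seq3)
        try:
            dated.append(
                ltr_divergence(aln, r=r, element_id=el.element_id, correction=correction)
            )
        except (SaturationError, EstimationError):
            undatable.append(el.element_id)
    return dated, undatable


def classify_solo_ltrs(
    candidate_segments: Sequence[tuple[str, int, int]],
    full_elements: Sequence[LtrElementRow],
) -> tuple[list[tuple[str, int, int]], int]:
    """Screen candidate segments for solo-LTRs.

    A candidate (chrom, start, end), 0-based half-open, is a solo-LTR iff it
    overlaps no full-length element interval by >= 1 bp; touching intervals
    do not overlap. Returns (solo list, paired count = full-length elements).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for el in full_elements:
        by_chrom.setdefault(el.chrom, []).append((el.element_start, el.element_end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts_ends[chrom] = (
            np.array([s for s, _ in ivals]),
            np.array([e for _, e in ivals]),
        )
    solo = []
    for chrom, start, end in candidate_segments:
        if end <= start:
            raise ValidationError(f"empty candidate interval on {chrom}")
        if chrom not in starts_ends:
            solo.append((chrom, start, end))
            continue
        starts, ends = starts_ends[chrom]
        # overlap iff element_start < end and element_end > start
        if not np.any((starts < end) & (ends > start)):
            solo.append((chrom, start, end))
    return solo, len(full_elements)


def solo_paired_ratio(n_solo: int, n_paired: int) -> float:
    """Solo-LTR : paired-LTR count ratio, reported to 2 decimals."""
    if n_paired <= 0:
        raise EstimationError("solo:paired ratio undefined with zero paired elements")
    if n_solo < 0:
        raise ValidationError("negative solo count")
    return round(n_solo / n_paired, 2)


def transposition_rate_curve(
    divergences: Iterable[LtrDivergence | float],
    bin_width: float = 1e5,
    horizon: float = 1e7,
) -> RateCurve:
    """Bin insertion times into half-open [i*w, (i+1)*w) bins up to ``horizon``.

    The accumulation curve is the cumulative insertion count running from the
    present toward the past. Elements with T >= horizon are excluded from the
    bins and reported separately.
    """
    times = np.array(
        [d.T if isinstance(d, LtrDivergence) else float(d) for d in divergences]
    )
    if np.any(times < 0):
        raise ValidationError("negative insertion time")
    n_bins = int(round(horizon / bin_width))
    in_range = times < horizon
    idx = np.floor(times[in_range] / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    return RateCurve(
        bin_width=bin_width,
        horizon=horizon,
        counts=counts,
        accumulation=np.cumsum(counts),
        n_excluded=int(np.sum(~in_range)),
    )


def superfamily_masses(
    bp_by_superfamily: Mapping[str, float],
    genome_length: float,
    counts_by_superfamily: Mapping[str, int] | None = None,
) -> tuple[list[SuperfamilyMass], float | None]:
    """Per-superfamily genome mass plus the Gypsy:Copia fold ratio.

    Percentages are bp / genome_length * 100 to 2 decimals; the fold ratio is
    bp_Gypsy / bp_Copia to 2 decimals (None when Copia mass is zero/absent).
    """
    if genome_length <= 0:
        raise ValidationError("genome length must be positive")
    counts_by_superfamily = counts_by_superfamily or {}
    masses = [
        SuperfamilyMass(
            superfamily=sf,
            total_bp=bp,
            fraction_of_genome=round(bp / genome_length * 100.0, 2),
            n_elements=counts_by_superfamily.get(sf, 0),
        )
        for sf, bp in bp_by_superfamily.items()
    ]
    gypsy = bp_by_superfamily.get("Gypsy", 0.0)
    copia = bp_by_superfamily.get("Copia", 0.0)
    fold = round(gypsy / copia, 2) if copia > 0 else None
    return masses, fold


def element_masses(
    elements: Sequence[LtrElementRow],
) -> tuple[dict[str, float], dict[str, int]]:
    """Aggregate total bp and element counts per superfamily."""
    bp: dict[str, float] = {}
    counts: dict[str, int] = {}
    for el in elements:
        bp[el.superfamily] = bp.get(el.superfamily, 0.0) + el.length
        counts[el.superfamily] = counts.get(el.superfamily, 0) + 1
    return bp, counts
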