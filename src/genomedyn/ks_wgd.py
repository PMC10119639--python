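"""Ks estimation, collinear-block chaining, Ks-peak detection and WGD dating.

The synonymous-rate estimator is Nei & Gojobori's (1986) counting method:
per-codon fractional synonymous sites, shortest-pathway averaging for codons
differing at more than one position, and a Jukes-Cantor multiple-hit
correction d = -(3/4) ln(1 - (4/3) p).

Conventions (documented choices): synonymous-site fractions are counted out
of 3 per codon position with changes to stop codons treated as
nonsynonymous; substitution pathways passing through a stop codon are
excluded from the pathway average, falling back to all pathways when every
pathway is blocked.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable
from scipy.stats import gaussian_kde

from .errors import EstimationError, ValidationError

__all__ = [
    "SENSE_CODONS",
    "KsResult",
    "Anchor",
    "CollinearBlock",
    "KsPeak",
    "KsPeakSet",
    "WgdDate",
    "ks_ng86",
    "remove_tandem_pairs",
    "find_collinear_blocks",
    "block_median_ks",
    "ks_distribution_peaks",
    "date_wgd",
    "syntenic_depth_ratio",
]

# ---------------------------------------------------------------------------
# Genetic code and NG86 codon-pair tables

_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))
_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_BASES = "ACGT"


def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous-site count s(c) for one sense codon (0..3).

    At each of the 3 positions the fraction of the 3 possible point changes
    that preserve the amino acid is accumulated; changes to stop codons count
    as nonsynonymous.
    """
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; orderings that
    pass through a stop codon are discarded (all orderings are used if every
    one is blocked). Identical codons give (0, 0).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _AA[cur] == _AA[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid if valid else blocked
    sd_avg = sum(p[0] for p in pool) / len(pool)
    nd_avg = sum(p[1] for p in pool) / len(pool)
    return sd_avg, nd_avg


_TABLES: dict[str, np.ndarray] = {}


def _codon_tables() -> dict[str, np.ndarray]:
    """Lazily built per-codon site fractions and 61x61 pathway-count tables."""
    if not _TABLES:
        n = len(SENSE_CODONS)
        s = np.array([synonymous_site_fraction(c) for c in SENSE_CODONS])
        sd = np.zeros((n, n))
        nd = np.zeros((n, n))
        for i, ca in enumerate(SENSE_CODONS):
            for j, cb in enumerate(SENSE_CODONS):
                sd[i, j], nd[i, j] = pathway_counts(ca, cb)
        _TABLES["s"] = s
        _TABLES["sd"] = sd
        _TABLES["nd"] = nd
    return _TABLES


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; requires p < 0.75."""
    if p >= 0.75:
        raise EstimationError(f"proportion {p} is at or beyond JC saturation (0.75)")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class KsResult:
    """NG86 output for one aligned in-frame pair."""

    ks: float               # nan when saturated_s
    ka: float               # nan when saturated_n
    s_sites: float          # averaged synonymous sites
    n_sites: float          # averaged nonsynonymous sites
    sd: float               # synonymous differences
    nd: float               # nonsynonymous differences
    ps: float
    pn: float
    n_codons_used: int
    saturated_s: bool = False
    saturated_n: bool = False


def _iter_codon_pairs(seq_a: str, seq_b: str):
    if len(seq_a) != len(seq_b):
        raise ValidationError("aligned sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise ValidationError("alignment length is not a multiple of 3")
    for i in range(0, len(seq_a), 3):
        yield seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()


def ks_ng86(seq_a: str, seq_b: str) -> KsResult:
    """Ks and Ka for one in-frame aligned pair by NG86 counting.

    Codons with a gap or ambiguous base in either sequence, and stop codons,
    are excluded. Saturation (ps or pn >= 0.75) sets a flag and NaN rather
    than a number.
    """
    t = _codon_tables()
    s_a = s_b = 0.0
    codons_used = 0
    sd_tot = nd_tot = 0.0
    for ca, cb in _iter_codon_pairs(seq_a, seq_b):
        if ca not in _CODON_INDEX or cb not in _CODON_INDEX:
            continue  # gap, N, or stop codon
        ia, ib = _CODON_INDEX[ca], _CODON_INDEX[cb]
        s_a += t["s"][ia]
        s_b += t["s"][ib]
        sd_tot += t["sd"][ia, ib]
        nd_tot += t["nd"][ia, ib]
        codons_used += 1
    if codons_used == 0:
        raise EstimationError("no comparable codons in the alignment")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * codons_used - s_sites
    ps = sd_tot / s_sites if s_sites > 0 else 0.0
    pn = nd_tot / n_sites if n_sites > 0 else 0.0
    sat_s = ps >= 0.75
    sat_n = pn >= 0.75
    return KsResult(
        ks=math.nan if sat_s else -0.75 * math.log(1 - (4.0 / 3.0) * ps) + 0.0,
        ka=math.nan if sat_n else -0.75 * math.log(1 - (4.0 / 3.0) * pn) + 0.0,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd_tot,
        nd=nd_tot,
        ps=ps,
        pn=pn,
        n_codons_used=codons_used,
        saturated_s=sat_s,
        saturated_n=sat_n,
    )


# ---------------------------------------------------------------------------
# Tandem filtering


def remove_tandem_pairs(
    pairs: Sequence[tuple[str, str]],
    gene_positions: Mapping[str, tuple[str, int]],
    max_rank_gap: int = 5,
) -> list[tuple[str, str]]:
    """Drop pairs whose genes sit on one chromosome within ``max_rank_gap`` ranks.

    ``gene_positions`` maps gene id -> (chromosome, gene-order rank).
    """
    kept = []
    for a, b in pairs:
        ca, ra = gene_positions[a]
        cb, rb = gene_positions[b]
        if ca == cb and abs(ra - rb) <= max_rank_gap:
            continue
        kept.append((a, b))
    return kept


# ---------------------------------------------------------------------------
# Collinear block chaining


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair located by gene-order rank in each genome."""

    rank_a: int
    rank_b: int
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.rank_a < 0 or self.rank_b < 0:
            raise ValidationError("anchor ranks must be non-negative")


@dataclass
class CollinearBlock:
    """A maximal monotone chain of anchors with an optional median Ks."""

    anchors: list[Anchor]
    orientation: str  # "same" | "inverted"
    median_ks: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


def _best_chain(anchors: list[Anchor], max_rank_gap: int, inverted: bool):
    """Longest chain strictly increasing in rank_a and monotone in rank_b.

    O(n^2) dynamic programming; consecutive anchors must be within
    ``max_rank_gap`` on both axes. Deterministic: anchors pre-sorted, ties
    resolved toward the earliest predecessor.
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    sign = -1 if inverted else 1
    for j in range(n):
        aj, bj = anchors[j].rank_a, anchors[j].rank_b
        for i in range(n):
            if i == j:
                continue
            ai, bi = anchors[i].rank_a, anchors[i].rank_b
            da = aj - ai
            db = sign * (bj - bi)
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                if best_len[i] + 1 > best_len[j]:
                    best_len[j] = best_len[i] + 1
                    prev[j] = i
    end = int(np.argmax(best_len))  # first maximum -> deterministic
    chain = []
    k = end
    while k != -1:
        chain.append(anchors[k])
        k = prev[k]
    chain.reverse()
    return chain


def find_collinear_blocks(
    anchors: Iterable[Anchor],
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Greedy repeated extraction of maximal monotone anchor chains.

    Each round finds the single best chain over the remaining anchors in
    both orientations (ties prefer "same"), emits it if it has at least
    ``min_anchors`` anchors, removes its anchors, and repeats. Anchors join
    at most one block.
    """
    remaining = sorted(set(anchors), key=lambda a: (a.rank_a, a.rank_b))
    blocks: list[CollinearBlock] = []
    while len(remaining) >= min_anchors:
        chain_same = _best_chain(remaining, max_rank_gap, inverted=False)
        chain_inv = _best_chain(remaining, max_rank_gap, inverted=True)
        if len(chain_inv) > len(chain_same):
            chain, orientation = chain_inv, "inverted"
        else:
            chain, orientation = chain_same, "same"
        if len(chain) < min_anchors:
            break
        blocks.append(CollinearBlock(anchors=chain, orientation=orientation))
        chain_set = set(chain)
        remaining = [a for a in remaining if a not in chain_set]
    return blocks


def block_median_ks(
    block: CollinearBlock, ks_by_pair: Mapping[str, float]
) -> float | None:
    """Median Ks over a block's anchors; saturated (NaN) values excluded.

    Returns None (block undatable) when every anchor is saturated or
    unmeasured. An even count takes the mean of the middle two.
    """
    values = []
    for anchor in block.anchors:
        v = ks_by_pair.get(anchor.pair_id, math.nan)
        if v is not None and not math.isnan(v):
            values.append(v)
    if not values:
        return None
    return float(np.median(values))


# ---------------------------------------------------------------------------
# Ks peak detection and proportional WGD dating


@dataclass(frozen=True)
class KsPeak:
    location: float
    height: float
    weight: float


@dataclass
class KsPeakSet:
    peaks: list[KsPeak]
    bandwidth: float
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    n_values: int = 0


def ks_distribution_peaks(
    values: Iterable[float],
    ks_max: float = 2.0,
    bandwidth: float | None = None,
    grid_points: int = 512,
    min_height_fraction: float = 0.05,
    min_values: int = 30,
) -> KsPeakSet:
    """Find Ks-distribution peaks by Gaussian KDE plus local-maximum scan.

    Values outside (0, ks_max] are discarded. Bandwidth follows Silverman's
    rule unless given explicitly (as an absolute bandwidth). Peaks are strict
    local maxima on the evaluation grid with height at least
    ``min_height_fraction`` of the global maximum; each peak's weight is the
    density mass of its basin (between flanking local minima).
    """
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    vals = vals[(vals > 0) & (vals <= ks_max)]
    if len(vals) < min_values:
        raise EstimationError(
            f"only {len(vals)} Ks values in (0, {ks_max}]; need >= {min_values}"
        )
    grid = np.linspace(0.0, ks_max, grid_points + 1)[1:]  # (0, ks_max]
    std = float(np.std(vals, ddof=1))
    if std < 1e-12 * max(1.0, float(np.abs(vals).max())):
        # Degenerate sample: every value identical; the peak is that value.
        loc = float(vals[0])
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - loc))] = 1.0
        return KsPeakSet(
            peaks=[KsPeak(location=loc, height=1.0, weight=1.0)],
            bandwidth=0.0,
            grid=grid,
            density=density,
            n_values=len(vals),
        )
    if bandwidth is None:
        kde = gaussian_kde(vals, bw_method="silverman")
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth / std)
    h = float(np.sqrt(kde.covariance[0, 0]))
    density = kde(grid)
    floor = min_height_fraction * density.max()
    is_max = np.zeros(len(grid), dtype=bool)
    is_max[1:-1] = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    peak_idx = np.flatnonzero(is_max & (density >= floor))
    # Basin boundaries: local minima (plus grid edges) between peaks.
    is_min = np.zeros(len(grid), dtype=bool)
    is_min[1:-1] = (density[1:-1] <= density[:-2]) & (density[1:-1] <= density[2:])
    min_idx = np.flatnonzero(is_min)
    dx = grid[1] - grid[0]
    peaks = []
    for pi in peak_idx:
        left_candidates = min_idx[min_idx < pi]
        right_candidates = min_idx[min_idx > pi]
        lo = int(left_candidates.max()) if len(left_candidates) else 0
        hi = int(right_candidates.min()) if len(right_candidates) else len(grid) - 1
        weight = float(density[lo : hi + 1].sum() * dx)
        peaks.append(
            KsPeak(location=float(grid[pi]), height=float(density[pi]), weight=weight)
        )
    return KsPeakSet(
        peaks=peaks, bandwidth=h, grid=grid, density=density, n_values=len(vals)
    )


@dataclass(frozen=True)
class WgdDate:
    """Proportional dating of a duplication event against a calibration peak."""

    ks_event: float
    ks_cal: float
    t_cal: float   # Mya
    t_event: float  # Mya, rounded to 2 decimals

    def __post_init__(self) -> None:
        expected = self.t_cal * self.ks_event / self.ks_cal
        if abs(self.t_event - round(expected, 2)) > 1e-9:
            raise ValidationError("t_event inconsistent with proportional formula")


def date_wgd(ks_event: float, ks_cal: float = 1.51, t_cal: float = 117.0) -> WgdDate:
    """Date an event peak proportionally: t_event = t_cal * ks_event / ks_cal.

    Defaults calibrate against the core-eudicot gamma triplication (Ks 1.51
    placed at 117 Mya).
    """
    if ks_cal <= 0:
        raise ValidationError("calibration Ks must be positive")
    if ks_event < 0:
        raise ValidationError("event Ks must be non-negative")
    t_event = round(t_cal * ks_event / ks_cal, 2)
    return WgdDate(ks_event=ks_event, ks_cal=ks_cal, t_cal=t_cal, t_event=t_event)


def syntenic_depth_ratio(
    blocks: Sequence[CollinearBlock],
    n_genes_a: int,
    n_genes_b: int,
) -> str:
    """Modal syntenic depth ratio "dA:dB" between two gene orders.

    The depth of a gene is the number of blocks whose rank span covers it on
    its own axis; the reported ratio is the mode of the nonzero depths on
    each side.
    """
    if not blocks:
        raise EstimationError("no collinear blocks: syntenic depth undefined")
    depth_a = np.zeros(n_genes_a, dtype=int)
    depth_b = np.zeros(n_genes_b, dtype=int)
    for blk in blocks:
        lo, hi = blk.span_a()
        depth_a[lo : hi + 1] += 1
        lo, hi = blk.span_b()
        depth_b[lo : hi + 1] += 1

    def _mode_nonzero(depths: np.ndarray) -> int:
        nz = depths[depths > 0]
        if len(nz) == 0:
            raise EstimationError("no covered genes on one axis")
        counts = np.bincount(nz)
        return int(np.argmax(counts))

    return f"{_mode_nonzero(depth_a)}:{_mode_nonzero(depth_b)}"
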