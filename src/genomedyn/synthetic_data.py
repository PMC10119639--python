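"""Seeded generators producing inputs with the structure each stage assumes.

Every generator takes a seed (or an already-spawned numpy Generator) and is
byte-deterministic for a fixed seed. Each emits a truth table alongside the
data so parameter-recovery tests can compare estimates against the planted
ground truth:

* an LTR landscape whose paired terminal repeats diverged for a known time
  under Jukes-Cantor substitution at a known neutral rate;
* in-frame paralog pairs whose measured Ks was driven to a target sampled
  from a mixture of peaks (synonymous-only substitutions);
* diploid genotypes under partial selfing with a known inbreeding
  coefficient F;
* a k-mer depth histogram with a Poisson coverage peak and a low-depth
  error tail;
* gene-order anchors with planted collinear blocks plus uniform noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import CapacityError, ValidationError
from .io_formats import GenotypeTable, KmerHistogram, LtrElementRow, SequenceRecord
from .ks_wgd import SENSE_CODONS, _CODON_INDEX, _codon_tables, ks_ng86
from .ks_wgd import Anchor, CollinearBlock

__all__ = [
    "LtrTruthRecord",
    "SelfingTruth",
    "simulate_ltr_landscape",
    "simulate_paralog_pairs",
    "simulate_selfing_genotypes",
    "simulate_kmer_histogram",
    "simulate_gene_orders",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LtrTruthRecord:
    element_id: str
    true_insertion_time: float   # years
    superfamily: str
    is_solo: bool

    def __post_init__(self) -> None:
        if self.true_insertion_time < 0:
            raise ValidationError("negative true insertion time")


@dataclass(frozen=True)
class SelfingTruth:
    F_true: float
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.F_true <= 1.0):
            raise ValidationError("F_true must be in [0, 1]")
        if np.any(self.allele_freqs <= 0) or np.any(self.allele_freqs >= 1):
            raise ValidationError("allele frequencies must lie in (0, 1)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _to_string(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def evolve_jc(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch of length ``d`` substitutions/site.

    Substitution-only (sequence length preserved): each site ends in a
    specific different base with probability (1 - exp(-4d/3)) / 4.
    """
    if d < 0:
        raise ValidationError("negative branch length")
    p_each = (1.0 - math.exp(-4.0 * d / 3.0)) / 4.0
    u = rng.random(len(codes))
    changed = u < 3.0 * p_each
    # uniformly one of the three other bases
    offsets = rng.integers(1, 4, size=len(codes), dtype=np.uint8)
    out = codes.copy()
    out[changed] = (codes[changed] + offsets[changed]) % 4
    return out


def simulate_ltr_landscape(
    genome_length: int = 15_000_000,
    n_elements: int = 500,
    time_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    r: float = 1.33e-9,
    ltr_length: int = 5_000,
    internal_length: int = 2_000,
    solo_fraction: float = 0.0,
    seed=0,
    chrom_id: str = "chr1",
) -> tuple[
    SequenceRecord,
    list[LtrElementRow],
    list[tuple[str, int, int]],
    list[LtrTruthRecord],
]:
    """Plant LTR retrotransposons of known age into a random genome.

    Each full-length element is built from one ancestral terminal repeat
    whose two copies evolve independently for the element's age t at rate r
    (per-branch divergence r*t, pairwise expectation 2rt). ``solo_fraction``
    of the elements are emitted as single-LTR segments (candidate solo-LTRs)
    and omitted from the full-length table. Defaults mirror the recovery
    study conditions: 500 elements, 5-kb LTRs, ages uniform on [0, 5 My],
    r = 1.33e-9/site/year.
    """
    rng = _rng(seed)
    if time_sampler is None:
        time_sampler = lambda g, n: g.uniform(0.0, 5e6, size=n)
    full_len = 2 * ltr_length + internal_length
    if n_elements * full_len > genome_length / 2:
        raise CapacityError(
            f"{n_elements} elements of {full_len} bp exceed half of "
            f"{genome_length} bp; enlarge the genome or shrink the request"
        )
    n_solo = int(round(solo_fraction * n_elements))
    is_solo = np.zeros(n_elements, dtype=bool)
    if n_solo:
        is_solo[rng.choice(n_elements, size=n_solo, replace=False)] = True
    lengths = np.where(is_solo, ltr_length, full_len)
    ages = np.asarray(time_sampler(rng, n_elements), dtype=float)
    if np.any(ages < 0):
        raise ValidationError("time sampler produced a negative age")

    # non-overlapping placement: distribute the slack uniformly between
    # elements laid out left to right
    slack = genome_length - int(lengths.sum())
    cuts = np.sort(rng.integers(0, slack + 1, size=n_elements))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths)[:-1]))

    genome = _random_bases(rng, genome_length)
    rows: list[LtrElementRow] = []
    candidates: list[tuple[str, int, int]] = []
    truth: list[LtrTruthRecord] = []
    for i in range(n_elements):
        eid = f"elem{i:04d}"
        t = float(ages[i])
        sf = "Gypsy" if rng.random() < 0.85 else "Copia"
        ancestral = _random_bases(rng, ltr_length)
        d = r * t
        copy5 = evolve_jc(ancestral, d, rng)
        start = int(starts[i])
        if is_solo[i]:
            genome[start : start + ltr_length] = copy5
            candidates.append((chrom_id, start, start + ltr_length))
        else:
            copy3 = evolve_jc(ancestral, d, rng)
            genome[start : start + ltr_length] = copy5
            genome[
                start + ltr_length + internal_length : start + full_len
            ] = copy3
            rows.append(
                LtrElementRow(
                    element_id=eid,
                    chrom=chrom_id,
                    element_start=start,
                    element_end=start + full_len,
                    ltr5_start=start,
                    ltr5_end=start + ltr_length,
                    ltr3_start=start + ltr_length + internal_length,
                    ltr3_end=start + full_len,
                    superfamily=sf,
                )
            )
        truth.append(
            LtrTruthRecord(
                element_id=eid,
                true_insertion_time=t,
                superfamily=sf,
                is_solo=bool(is_solo[i]),
            )
        )
    record = SequenceRecord(id=chrom_id, sequence=_to_string(genome))
    return record, rows, candidates, truth


# ---------------------------------------------------------------------------
# Paralog pairs at planted Ks


def _synonymous_neighbours() -> list[list[tuple[int, int]]]:
    """For each sense codon index: (position, replacement-codon index) of
    every synonymous single-nucleotide change (stops excluded)."""
    from .ks_wgd import _AA, STOP_CODONS

    out: list[list[tuple[int, int]]] = []
    for codon in SENSE_CODONS:
        neigh = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
                    neigh.append((pos, _CODON_INDEX[alt]))
        out.append(neigh)
    return out


_SYN_NEIGHBOURS: list[list[tuple[int, int]]] | None = None


def simulate_paralog_pairs(
    peaks: Sequence[tuple[float, float, float]] = ((0.13, 0.03, 0.5), (0.6, 0.03, 0.5)),
    n_pairs: int = 1000,
    n_codons: int = 300,
    seed=0,
    max_attempts: int = 5,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], list[float]]:
    """Generate in-frame aligned pairs whose measured Ks hits mixture targets.

    ``peaks`` is a list of (mean Ks, sd, weight) components with weights
    summing to 1. For each pair a target Ks is sampled from the mixture and
    synonymous-only single-nucleotide codon substitutions are applied to one
    copy until the NG86-measured Ks of the pair first reaches the target;
    the realized (measured) Ks is recorded as the truth value. Pairs whose
    target cannot be reached (synonymous saturation) are regenerated with a
    warning.
    """
    global _SYN_NEIGHBOURS
    if _SYN_NEIGHBOURS is None:
        _SYN_NEIGHBOURS = _synonymous_neighbours()
    weights = np.array([w for _, _, w in peaks], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError("mixture weights must sum to 1")
    if any(mu < 0 for mu, _, _ in peaks):
        raise ValidationError("mixture means must be non-negative")
    rng = _rng(seed)
    tables = _codon_tables()
    s_frac = tables["s"]
    sd_table = tables["sd"]
    n_codon_types = len(SENSE_CODONS)

    records: list[tuple[SequenceRecord, SequenceRecord]] = []
    realized: list[float] = []
    for pair_idx in range(n_pairs):
        comp = rng.choice(len(peaks), p=weights)
        mu, sd, _ = peaks[comp]
        if sd > 0:
            target = -1.0
            while target <= 0:
                target = rng.normal(mu, sd)
        else:
            target = mu  # a zero target yields identical sequences
        for attempt in range(max_attempts):
            codons_a = rng.integers(0, n_codon_types, size=n_codons)
            codons_b = codons_a.copy()
            s_a = float(s_frac[codons_a].sum())
            s_b = s_a
            sd_sum = 0.0
            ok = target == 0.0
            max_steps = 40 * n_codons
            for _ in range(max_steps):
                s_sites = (s_a + s_b) / 2.0
                ps = sd_sum / s_sites if s_sites > 0 else 0.0
                if ps < 0.75:
                    ks = -0.75 * math.log(1.0 - (4.0 / 3.0) * ps)
                    if ks >= target:
                        ok = True
                        break
                # one synonymous substitution on a random mutable codon of b
                pos = int(rng.integers(0, n_codons))
                neigh = _SYN_NEIGHBOURS[codons_b[pos]]
                if not neigh:
                    continue
                _, new_idx = neigh[int(rng.integers(0, len(neigh)))]
                old_idx = int(codons_b[pos])
                s_b += s_frac[new_idx] - s_frac[old_idx]
                sd_sum += (
                    sd_table[codons_a[pos], new_idx] - sd_table[codons_a[pos], old_idx]
                )
                codons_b[pos] = new_idx
            if ok:
                break
            warnings.warn(
                f"pair {pair_idx}: target Ks {target:.3f} beyond synonymous "
                "saturation for this codon composition; regenerating",
                stacklevel=2,
            )
        else:
            raise ValidationError(
                f"pair {pair_idx}: cannot reach target Ks {target:.3f}"
            )
        seq_a = "".join(SENSE_CODONS[i] for i in codons_a)
        seq_b = "".join(SENSE_CODONS[i] for i in codons_b)
        measured = ks_ng86(seq_a, seq_b).ks
        records.append(
            (
                SequenceRecord(id=f"pair{pair_idx:05d}_a", sequence=seq_a),
                SequenceRecord(id=f"pair{pair_idx:05d}_b", sequence=seq_b),
            )
        )
        realized.append(measured)
    return records, realized


# ---------------------------------------------------------------------------
# Selfing genotypes


def simulate_selfing_genotypes(
    n_ind: int = 30,
    n_sites: int = 50_000,
    freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    F_true: float = 0.84,
    seed=0,
    chrom_id: str = "chr1",
    pos_step: int = 50,
) -> tuple[GenotypeTable, SelfingTruth]:
    """Diploid genotypes under partial selfing with inbreeding ``F_true``.

    Per site with alternate-allele frequency p, genotypes are drawn with
    P(hom-ref) = (1-p)^2 + F p(1-p), P(het) = 2 p (1-p) (1-F),
    P(hom-alt) = p^2 + F p (1-p). Defaults mirror the study's sampling:
    30 individuals, 50k sites, F = 0.84.
    """
    if not (0.0 <= F_true <= 1.0):
        raise ValidationError("F_true must be in [0, 1]")
    rng = _rng(seed)
    if freq_sampler is None:
        freq_sampler = lambda g, n: g.uniform(0.05, 0.95, size=n)
    p = np.asarray(freq_sampler(rng, n_sites), dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValidationError("allele frequencies must lie in (0, 1)")
    het = (2.0 * p * (1.0 - p) * (1.0 - F_true))[:, None]
    hom_ref = ((1.0 - p) ** 2 + F_true * p * (1.0 - p))[:, None]
    u = rng.random((n_sites, n_ind))
    genotypes = np.where(u < hom_ref, 0, np.where(u < hom_ref + het, 1, 2)).astype(
        np.int8
    )
    table = GenotypeTable(
        individuals=[f"ind{i:02d}" for i in range(n_ind)],
        chrom=np.full(n_sites, chrom_id, dtype=object),
        pos=np.arange(n_sites, dtype=np.int64) * pos_step,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, 100.0),
        biallelic=np.ones(n_sites, dtype=bool),
        genotypes=genotypes,
        depth=np.full((n_sites, n_ind), 20, dtype=np.int32),
        gq=np.full((n_sites, n_ind), 99, dtype=np.int32),
    )
    return table, SelfingTruth(F_true=F_true, allele_freqs=p)


# ---------------------------------------------------------------------------
# k-mer histogram


def simulate_kmer_histogram(
    genome_size: int = 1_000_000,
    coverage: float = 20.0,
    error_kmer_fraction: float = 0.2,
    seed=0,
    k: int = 17,
) -> KmerHistogram:
    """Depth histogram with a Poisson coverage peak and a low-depth error tail.

    ``genome_size`` distinct genomic k-mers receive Poisson(coverage) depths;
    error k-mers (a fraction ``error_kmer_fraction`` of all distinct k-mers)
    sit at depth 1 or 2 (P(depth 2) = 0.2, the artifact's own error-tail
    assumption — the survey literature states none).
    """
    if coverage < 5:
        raise ValidationError("coverage must be at least 5 for a usable peak")
    if not (0.0 <= error_kmer_fraction < 1.0):
        raise ValidationError("error_kmer_fraction must be in [0, 1)")
    rng = _rng(seed)
    depths = rng.poisson(coverage, size=genome_size)
    counts = np.bincount(depths)
    n_err = int(round(error_kmer_fraction / (1.0 - error_kmer_fraction) * genome_size))
    if n_err:
        n_depth2 = rng.binomial(n_err, 0.2)
        if len(counts) < 3:
            counts = np.pad(counts, (0, 3 - len(counts)))
        counts[1] += n_err - n_depth2
        counts[2] += n_depth2
    nz = np.flatnonzero(counts[1:]) + 1  # drop unobserved depth 0
    return KmerHistogram(depth=nz.astype(np.int64), count=counts[nz].astype(np.int64), k=k)


# ---------------------------------------------------------------------------
# Gene orders with planted collinear blocks


@dataclass(frozen=True)
class PlantedBlock:
    start_a: int
    start_b: int
    n_anchors: int
    inverted: bool = False

    def anchors(self) -> list[Anchor]:
        if self.inverted:
            return [
                Anchor(self.start_a + j, self.start_b + self.n_anchors - 1 - j,
                       pair_id=f"planted_{self.start_a}_{j}")
                for j in range(self.n_anchors)
            ]
        return [
            Anchor(self.start_a + j, self.start_b + j,
                   pair_id=f"planted_{self.start_a}_{j}")
            for j in range(self.n_anchors)
        ]


def simulate_gene_orders(
    n_genes: int = 200,
    planted_blocks: Sequence[PlantedBlock | tuple] = (),
    noise_anchors: int = 50,
    seed=0,
) -> tuple[list[Anchor], list[CollinearBlock]]:
    """Anchors with planted strictly-monotone collinear runs plus uniform noise.

    ``planted_blocks`` entries are PlantedBlock objects or
    (start_a, start_b, n_anchors[, inverted]) tuples; blocks must not overlap
    on either genome. Noise anchors are uniform over the rank grid and never
    duplicate an existing anchor position.
    """
    rng = _rng(seed)
    blocks = [
        b if isinstance(b, PlantedBlock) else PlantedBlock(*b) for b in planted_blocks
    ]
    for axis, key_lo, key_n in (("A", "start_a", "n_anchors"), ("B", "start_b", "n_anchors")):
        spans = sorted(
            (getattr(b, key_lo), getattr(b, key_lo) + b.n_anchors) for b in blocks
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValidationError(f"planted blocks overlap on genome {axis}")
    anchors: list[Anchor] = []
    truth: list[CollinearBlock] = []
    for b in blocks:
        if b.start_a + b.n_anchors > n_genes or b.start_b + b.n_anchors > n_genes:
            raise ValidationError("planted block extends beyond the gene count")
        a_list = b.anchors()
        anchors.extend(a_list)
        truth.append(
            CollinearBlock(
                anchors=a_list, orientation="inverted" if b.inverted else "same"
            )
        )
    taken = {(a.rank_a, a.rank_b) for a in anchors}
    made = 0
    while made < noise_anchors:
        ra, rb = int(rng.integers(0, n_genes)), int(rng.integers(0, n_genes))
        if (ra, rb) in taken:
            continue
        taken.add((ra, rb))
        anchors.append(Anchor(ra, rb, pair_id=f"noise_{made}"))
        made += 1
    return anchors, truth
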