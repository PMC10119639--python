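"""SNP filter cascade, inbreeding/selfing estimation, and windowed diversity.

The filter cascade reproduces a post-variant-calling cleanup: quality floor,
per-call depth/GQ masking, indel proximity, missingness, minor-allele
frequency, exact Hardy-Weinberg test, and a repeat mask, applied in a fixed
order with per-rule accounting. Downstream statistics are the moment
inbreeding estimator F = 1 - O/E per individual, the equilibrium selfing
rate s = 2F/(1+F), and vcftools-convention windowed nucleotide diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, EstimationError, ValidationError
from .io_formats import GenotypeTable

__all__ = [
    "FilterConfig",
    "InbreedingRecord",
    "DiversityWindow",
    "filter_snps",
    "hwe_exact_pvalue",
    "individual_inbreeding",
    "selfing_rate",
    "sliding_pi",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP filter cascade (defaults per the study design)."""

    min_qual: float = 20.0
    depth_band_factor: float = 3.0     # keep mean/3 <= DP <= 3*mean per site
    indel_margin: int = 5              # bp; drop SNPs at or within this of an indel
    max_missing_fraction: float = 0.3  # vcftools max-missing 0.7
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    min_gq: int = 10

    def __post_init__(self) -> None:
        if self.depth_band_factor <= 1:
            raise ConfigError("depth band factor must exceed 1")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ConfigError("max_missing_fraction must be in [0, 1]")
        for name in ("min_qual", "indel_margin", "min_maf", "hwe_alpha", "min_gq"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class InbreedingRecord:
    individual: str
    F: float
    s: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.F <= 1.0 + 1e-12):
            raise ValidationError(f"F = {self.F} outside [-1, 1]")


@dataclass(frozen=True)
class DiversityWindow:
    chrom: str
    start: int     # 0-based half-open
    end: int
    n_sites: int   # SNP sites contributing
    pi: float


def hwe_exact_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (conditional on allele counts).

    Sums, over the distribution of heterozygote counts conditional on the
    observed allele counts, the probabilities of all outcomes no more likely
    than the observed one (Wigginton-style two-sided exact test).
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValidationError("negative genotype count")
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible heterozygote counts share the parity of n_rare
    het_values = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    # unnormalised conditional probabilities via the standard recurrence
    log_probs = {}
    h0 = het_values[0]
    log_probs[h0] = 0.0
    for h in het_values[1:]:
        # P(h) / P(h-2) = 4 * hom_r(h-2) * hom_c(h-2) / (h * (h-1))
        prev = h - 2
        hom_r_prev = (n_rare - prev) // 2
        hom_c_prev = n - prev - hom_r_prev
        log_probs[h] = log_probs[prev] + math.log(
            4.0 * hom_r_prev * hom_c_prev / (h * (h - 1))
        )
    mx = max(log_probs.values())
    probs = {h: math.exp(lp - mx) for h, lp in log_probs.items()}
    total = sum(probs.values())
    p_obs = probs.get(n_het)
    if p_obs is None:
        raise ValidationError("heterozygote count inconsistent with allele counts")
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / total)


def _site_mean_depth(depth_row: np.ndarray, gt_row: np.ndarray) -> float:
    """Mean depth over calls that are non-missing and depth-annotated."""
    ok = (gt_row >= 0) & (depth_row >= 0)
    if not np.any(ok):
        return math.nan
    return float(depth_row[ok].mean())


def filter_snps(
    table: GenotypeTable,
    cfg: FilterConfig | None = None,
    indel_positions: Mapping[str, Sequence[int]] | None = None,
    repeat_mask: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[GenotypeTable, dict[str, int]]:
    """Apply the SNP filter cascade in its fixed order.

    Rules, in order: (1) keep biallelic SNPs with QUAL >= min_qual; (2) mask
    individual calls with depth outside (site-mean/3, 3*site-mean) or
    GQ < min_gq as missing; (3) drop sites at or within ``indel_margin`` bp
    of an indel; (4) drop sites with missing fraction > max_missing_fraction;
    (5) drop sites with MAF < min_maf; (6) drop sites failing the exact HWE
    test at ``hwe_alpha``; (7) drop sites inside the repeat mask. Returns the
    filtered table and the per-rule removal log (rule 2 counts masked calls).
    """
    cfg = cfg or FilterConfig()
    log: dict[str, int] = {}
    n0 = table.n_sites

    # (1) biallelic SNPs with sufficient site quality
    qual_ok = ~np.isnan(table.qual) & (table.qual >= cfg.min_qual)
    keep = table.biallelic & qual_ok
    log["biallelic_qual"] = int(n0 - keep.sum())
    table = table.take_sites(keep)

    # (2) per-call depth band and genotype quality masking
    genotypes = table.genotypes.copy()
    masked = 0
    for s in range(table.n_sites):
        gt_row = genotypes[s]
        dp_row = table.depth[s]
        gq_row = table.gq[s]
        mean_dp = _site_mean_depth(dp_row, gt_row)
        bad = np.zeros(len(gt_row), dtype=bool)
        if not math.isnan(mean_dp) and mean_dp > 0:
            has_dp = dp_row >= 0
            bad |= has_dp & (
                (dp_row < mean_dp / cfg.depth_band_factor)
                | (dp_row > cfg.depth_band_factor * mean_dp)
            )
        bad |= (gq_row >= 0) & (gq_row < cfg.min_gq)
        bad &= gt_row >= 0
        masked += int(bad.sum())
        gt_row[bad] = -1
    log["depth_gq_masked_calls"] = masked
    table = GenotypeTable(
        individuals=table.individuals,
        chrom=table.chrom,
        pos=table.pos,
        ref=table.ref,
        alt=table.alt,
        qual=table.qual,
        biallelic=table.biallelic,
        genotypes=genotypes,
        depth=table.depth,
        gq=table.gq,
    )

    # (3) proximity to indels
    if indel_positions:
        keep = np.ones(table.n_sites, dtype=bool)
        for s in range(table.n_sites):
            near = indel_positions.get(str(table.chrom[s]), ())
            for ip in near:
                if abs(int(table.pos[s]) - int(ip)) <= cfg.indel_margin:
                    keep[s] = False
                    break
        log["near_indel"] = int((~keep).sum())
        table = table.take_sites(keep)
    else:
        log["near_indel"] = 0

    # (4) missingness
    missing_frac = (table.genotypes < 0).mean(axis=1)
    keep = missing_frac <= cfg.max_missing_fraction
    log["missingness"] = int((~keep).sum())
    table = table.take_sites(keep)

    # (5) minor allele frequency
    gt = np.ma.masked_less(table.genotypes, 0)
    with np.errstate(invalid="ignore"):
        p = gt.mean(axis=1).filled(np.nan) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = ~np.isnan(maf) & (maf >= cfg.min_maf)
    log["maf"] = int((~keep).sum())
    table = table.take_sites(keep)

    # (6) exact HWE
    keep = np.ones(table.n_sites, dtype=bool)
    for s in range(table.n_sites):
        row = table.genotypes[s]
        n_hom_ref = int(np.sum(row == 0))
        n_het = int(np.sum(row == 1))
        n_hom_alt = int(np.sum(row == 2))
        if hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt) < cfg.hwe_alpha:
            keep[s] = False
    log["hwe"] = int((~keep).sum())
    table = table.take_sites(keep)

    # (7) repeat mask
    if repeat_mask:
        keep = np.ones(table.n_sites, dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in repeat_mask:
            by_chrom.setdefault(chrom, []).append((start, end))
        for s in range(table.n_sites):
            for start, end in by_chrom.get(str(table.chrom[s]), ()):
                if start <= table.pos[s] < end:
                    keep[s] = False
                    break
        log["repeat_mask"] = int((~keep).sum())
        table = table.take_sites(keep)
    else:
        log["repeat_mask"] = 0

    return table, log


def individual_inbreeding(
    table: GenotypeTable,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Per-individual moment inbreeding estimator F = 1 - O/E.

    O is the individual's observed heterozygous-call count over its
    non-missing sites; E is the sum of 2 p(1-p) over the same sites, with p
    the sample allele frequency from all non-missing calls at the site.
    Individuals with no informative site (E = 0) are flagged instead of
    receiving an F. Requires at least two individuals.
    """
    if table.n_individuals < 2:
        raise EstimationError("inbreeding requires at least two individuals")
    gt = table.genotypes
    nonmissing = gt >= 0
    with np.errstate(invalid="ignore"):
        p = np.where(
            nonmissing.sum(axis=1) > 0,
            np.where(gt < 0, 0, gt).sum(axis=1) / (2.0 * nonmissing.sum(axis=1)),
            np.nan,
        )
    exp_het_site = 2.0 * p * (1.0 - p)
    results: list[tuple[str, float]] = []
    flagged: list[str] = []
    for i, ind in enumerate(table.individuals):
        ok = nonmissing[:, i] & ~np.isnan(p)
        e = float(exp_het_site[ok].sum())
        if e == 0.0:
            flagged.append(ind)
            continue
        o = float(np.sum(gt[ok, i] == 1))
        results.append((ind, 1.0 - o / e))
    return results, flagged


def selfing_rate(F: float) -> float:
    """Equilibrium selfing rate s = 2F / (1 + F); requires F > -1."""
    if F <= -1.0:
        raise ValidationError(f"selfing rate undefined for F = {F} <= -1")
    return 2.0 * F / (1.0 + F)


def inbreeding_records(table: GenotypeTable) -> tuple[list[InbreedingRecord], list[str]]:
    """Convenience: per-individual (F, s) records plus flagged individuals."""
    fs, flagged = individual_inbreeding(table)
    records = [
        InbreedingRecord(individual=ind, F=f, s=selfing_rate(f)) for ind, f in fs
    ]
    return records, flagged


def sliding_pi(
    table: GenotypeTable,
    chrom_lengths: Mapping[str, int],
    window: int = 50_000,
    step: int = 25_000,
) -> list[DiversityWindow]:
    """Windowed nucleotide diversity, vcftools convention.

    Per SNP site with c alternate alleles among m non-missing alleles,
    pi_site = c (m - c) / C(m, 2); window pi sums site pi over the window and
    divides by the window length in bp (monomorphic and unobserved positions
    contribute zero). Windows start at multiples of ``step`` and must fit
    entirely on the chromosome; ``window`` must be a positive multiple of
    ``step``.
    """
    if window < step:
        raise ConfigError("window must be at least as large as step")
    if window % step != 0:
        raise ConfigError("window must be a multiple of step")
    gt = table.genotypes
    nonmissing = gt >= 0
    m = 2 * nonmissing.sum(axis=1)
    c = np.where(gt < 0, 0, gt).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(m >= 2, c * (m - c) / (m * (m - 1) / 2.0), 0.0)
    windows: list[DiversityWindow] = []
    for chrom, length in chrom_lengths.items():
        on_chrom = table.chrom == chrom
        pos = table.pos[on_chrom]
        pis = pi_site[on_chrom]
        start = 0
        while start + window <= length:
            in_win = (pos >= start) & (pos < start + window)
            windows.append(
                DiversityWindow(
                    chrom=chrom,
                    start=start,
                    end=start + window,
                    n_sites=int(in_win.sum()),
                    pi=float(pis[in_win].sum()) / window,
                )
            )
            start += step
    return windows
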