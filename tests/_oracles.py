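"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from first principles (exhaustive
enumeration or naive quadratic computation) and shares no code with the
implementation it audits.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# Global affine-gap alignment by exhaustive recursion (tiny strings only)


def best_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal global alignment score by recursion over all alignments.

    A gap of length L costs gap_open + (L-1) * gap_extend. States track
    whether the previous column was a gap in the same sequence.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + go(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "x" else gap_open
            options.append(cost + go(i + 1, j, "x"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "y" else gap_open
            options.append(cost + go(i, j + 1, "y"))
        return max(options)

    return go(0, 0, "m")


# ---------------------------------------------------------------------------
# NG86 codon counting by direct enumeration

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
SENSE_CODONS = sorted(_AA)


def syn_fraction(codon: str) -> float:
    """Synonymous sites of one codon: per position, synonymous changes / 3
    (changes to stop codons count as nonsynonymous)."""
    total = 0.0
    for pos in range(3):
        hits = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _AA[mutant] == _AA[codon]:
                hits += 1
        total += hits / 3.0
    return total


def pathway_sd_nd(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over shortest pathways.

    Pathways through stop codons are dropped (all pathways kept when every
    pathway is blocked); steps between sense codons are synonymous iff the
    amino acid is unchanged.
    """
    positions = [p for p in range(3) if ca[p] != cb[p]]
    if not positions:
        return (0.0, 0.0)
    kept, all_paths = [], []
    for order in itertools.permutations(positions):
        codon = ca
        sd = nd = 0
        stop_hit = False
        for pos in order:
            nxt = codon[:pos] + cb[pos] + codon[pos + 1 :]
            if nxt in _STOPS:
                stop_hit = True
                nd += 1
            elif codon in _STOPS:
                nd += 1
            elif _AA[codon] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            codon = nxt
        all_paths.append((sd, nd))
        if not stop_hit:
            kept.append((sd, nd))
    pool = kept if kept else all_paths
    return (
        sum(x for x, _ in pool) / len(pool),
        sum(y for _, y in pool) / len(pool),
    )


def ng86_ks_ka(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Full NG86 Ks/Ka by per-codon enumeration (no shared code)."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_total = n_total = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if ca in _STOPS or cb in _STOPS or ca not in _AA or cb not in _AA:
            continue
        s = (syn_fraction(ca) + syn_fraction(cb)) / 2.0
        s_total += s
        n_total += 3.0 - s
        d = pathway_sd_nd(ca, cb)
        sd += d[0]
        nd += d[1]
    ps, pn = sd / s_total, nd / n_total
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn)


# ---------------------------------------------------------------------------
# Longest monotone anchor chain by memoised recursion


def longest_chain_length(
    anchors: list[tuple[int, int]], max_rank_gap: int, inverted: bool = False
) -> int:
    """Length of the longest chain strictly increasing in rank_a and
    monotone in rank_b with both per-step gaps within ``max_rank_gap``."""
    pts = sorted(set(anchors))
    sign = -1 if inverted else 1

    @lru_cache(maxsize=None)
    def from_point(k: int) -> int:
        best = 1
        ak, bk = pts[k]
        for j, (aj, bj) in enumerate(pts):
            da, db = aj - ak, sign * (bj - bk)
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                best = max(best, 1 + from_point(j))
        return best

    return max((from_point(k) for k in range(len(pts))), default=0)


# ---------------------------------------------------------------------------
# Nucleotide diversity by naive pairwise comparison


def window_pi_naive(haplotype_alleles: list[list[int]], window_length: int) -> float:
    """Window pi from per-site haplotype allele lists (missing = absent).

    Each entry of ``haplotype_alleles`` is the list of non-missing alleles
    (0/1) observed at one SNP site inside the window; pi sums, per site, the
    fraction of differing haplotype pairs, divided by the window length.
    """
    total = 0.0
    for alleles in haplotype_alleles:
        diffs = pairs = 0
        for x, y in itertools.combinations(alleles, 2):
            pairs += 1
            if x != y:
                diffs += 1
        if pairs:
            total += diffs / pairs
    return total / window_length


# ---------------------------------------------------------------------------
# Exact HWE p-value by direct enumeration of the conditional distribution


def hwe_pvalue_enumeration(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact HWE test from multinomial probabilities conditional on allele
    counts, computed term by term with exact factorials."""
    n = n_het + n_hom_ref + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    probs = {}
    for h in range(min(n_ref, n_alt) + 1):
        if (n_ref - h) % 2:
            continue
        hr = (n_ref - h) // 2
        ha = (n_alt - h) // 2
        if hr < 0 or ha < 0 or hr + ha + h != n:
            continue
        probs[h] = (
            math.factorial(n)
            / (math.factorial(hr) * math.factorial(ha) * math.factorial(h))
            * 2**h
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / total
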