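import numpy as np
import pytest

from genomedyn.io_formats import GenotypeTable


def make_table(
    genotypes,
    qual=None,
    depth=None,
    gq=None,
    biallelic=None,
    pos=None,
    chrom="1",
    pos_step=100,
):
    """Build a GenotypeTable from a (n_sites, n_ind) genotype list."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = gt.shape
    if pos is None:
        pos = np.arange(n_sites, dtype=np.int64) * pos_step + 100
    return GenotypeTable(
        individuals=[f"s{i}" for i in range(n_ind)],
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, 100.0) if qual is None else np.asarray(qual, float),
        biallelic=np.ones(n_sites, bool) if biallelic is None else np.asarray(biallelic, bool),
        genotypes=gt,
        depth=np.full((n_sites, n_ind), 20, np.int32) if depth is None else np.asarray(depth, np.int32),
        gq=np.full((n_sites, n_ind), 99, np.int32) if gq is None else np.asarray(gq, np.int32),
    )


@pytest.fixture
def filter_toy():
    """Six sites crafted so rules 1, 3, 4, 5, 6 and 7 each remove one.

    12 individuals; positions (0-based) 100..600; an indel at 203 dooms the
    site at 200; a repeat-mask interval [590, 650) dooms the site at 600.
    """
    n = 12
    hwe_balanced = [0] * 3 + [1] * 6 + [2] * 3
    genotypes = [
        hwe_balanced,                     # pos 100: qual 10 -> rule 1
        hwe_balanced,                     # pos 200: 3 bp from indel -> rule 3
        [-1] * 4 + [0] * 4 + [1] * 4,     # pos 300: 4/12 missing -> rule 4
        [0] * n,                          # pos 400: MAF 0 -> rule 5
        [0] * 6 + [2] * 6,                # pos 500: no hets -> rule 6 (HWE)
        hwe_balanced,                     # pos 600: inside mask -> rule 7
    ]
    qual = [10.0, 100.0, 100.0, 100.0, 100.0, 100.0]
    table = make_table(genotypes, qual=qual, pos=[100, 200, 300, 400, 500, 600])
    indels = {"1": [203]}
    mask = [("1", 590, 650)]
    return table, indels, mask


@pytest.fixture
def allpass_toy():
    """Three well-behaved sites that survive every filter rule unchanged."""
    hwe_balanced = [0] * 3 + [1] * 6 + [2] * 3
    return make_table([hwe_balanced, hwe_balanced, hwe_balanced])
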