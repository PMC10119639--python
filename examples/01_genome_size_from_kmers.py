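"""Estimate a genome size from a k-mer depth histogram.

A 17-mer depth histogram from a short-read survey has an error tail at
depths 1-2 and a coverage peak near the sequencing depth. The genome size
is the total number of k-mer instances beyond the error tail divided by
the peak depth.
"""

from genomedyn import estimate_genome_size, find_main_peak
from genomedyn.synthetic_data import simulate_kmer_histogram

# a 1-Mb genome surveyed at 20x, with 20% of distinct k-mers being errors
hist = simulate_kmer_histogram(
    genome_size=1_000_000, coverage=20.0, error_kmer_fraction=0.2, seed=1
)

valley, peak = find_main_peak(hist)
est = estimate_genome_size(hist)

print(f"error-tail valley at depth {valley}, coverage peak at depth {peak}")
print(f"k-mer instances used: {est.total_kmers_used:,}")
print(f"estimated genome size: {est.genome_size:,.0f} bp (truth: 1,000,000)")
# The estimate divides the instance total above the valley by the peak
# depth; with a clean 20x peak it lands within a couple of percent of truth.
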