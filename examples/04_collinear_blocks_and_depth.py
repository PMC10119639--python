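"""Chain collinear blocks from gene-order anchors and read syntenic depth.

Homologous gene pairs (anchors) between two genomes are chained into
maximal runs that are strictly increasing on one axis and monotone on the
other. The modal number of blocks covering each gene — the syntenic depth
ratio — distinguishes, e.g., a 2:1 pattern after a lineage-specific WGD.
"""

from genomedyn import find_collinear_blocks, syntenic_depth_ratio
from genomedyn.ks_wgd import Anchor
from genomedyn.synthetic_data import simulate_gene_orders

anchors, truth = simulate_gene_orders(
    n_genes=200,
    planted_blocks=[(10, 40, 8), (60, 5, 10), (120, 150, 6, True)],
    noise_anchors=40,
    seed=2,
)
blocks = find_collinear_blocks(anchors, min_anchors=5, max_rank_gap=25)
print(f"{len(anchors)} anchors -> {len(blocks)} blocks "
      f"(planted: {len(truth)})")
for i, blk in enumerate(blocks):
    print(f"  block {i}: {blk.n_anchors} anchors, {blk.orientation}, "
          f"spans A{blk.span_a()} B{blk.span_b()}")

# a duplicated genome A against a single-copy B: every B region hit twice
dup = [Anchor(i, i, "") for i in range(10)] + [Anchor(i + 10, i, "") for i in range(10)]
depth_blocks = find_collinear_blocks(dup, min_anchors=5, max_rank_gap=25)
print("syntenic depth (duplicated A vs single-copy B):",
      syntenic_depth_ratio(depth_blocks, 20, 10))
# Prints 1:2 -- each A gene is covered once, each B gene twice, the
# signature read in reverse as 2:1 from the duplicated genome's side.
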