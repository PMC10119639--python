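"""Detect Ks peaks among paralog pairs and date a WGD proportionally.

Whole-genome duplications leave cohorts of paralog pairs with similar
synonymous divergence Ks; peaks in the Ks distribution mark duplication
events. A peak is dated against the core-eudicot gamma triplication
(Ks 1.51 placed at 117 Mya) by simple proportionality.
"""

from genomedyn import date_wgd, ks_distribution_peaks, ks_ng86
from genomedyn.synthetic_data import simulate_paralog_pairs

# two duplication cohorts: a recent event near Ks 0.13 and an older one at 0.6
pairs, _ = simulate_paralog_pairs(
    peaks=[(0.13, 0.03, 0.5), (0.6, 0.03, 0.5)], n_pairs=400, n_codons=300, seed=5
)
ks_values = [ks_ng86(a.sequence, b.sequence).ks for a, b in pairs]

peak_set = ks_distribution_peaks(ks_values)
print(f"KDE bandwidth {peak_set.bandwidth:.3f}; "
      f"{len(peak_set.peaks)} peaks detected:")
for p in sorted(peak_set.peaks, key=lambda q: q.location):
    print(f"  Ks = {p.location:.3f} (weight {p.weight:.2f})")

recent = min(p.location for p in peak_set.peaks)
date = date_wgd(recent, ks_cal=1.51, t_cal=117.0)
print(f"recent peak at Ks {recent:.3f} dates to {date.t_event} Mya "
      f"(gamma calibration: Ks {date.ks_cal} = {date.t_cal} Mya)")
# With the recent cohort planted at Ks 0.13 the inferred age falls near
# 10 Mya, the same arithmetic that places a Ks-0.125 peak at 9.69 Mya.
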