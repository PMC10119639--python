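"""Genome-size estimation from a k-mer depth histogram.

The estimate follows the survey identity
``genome size = total number of k-mer instances / peak depth``,
with an optional low-depth cutoff that excludes the sequencing-error tail
from the instance total. Peak finding is valley-then-argmax on the raw
histogram: the valley is the first local minimum of count against depth and
the peak the count argmax at depths beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError
from .io_formats import KmerHistogram

__all__ = ["GenomeSizeEstimate", "find_main_peak", "estimate_genome_size"]


@dataclass(frozen=True)
class GenomeSizeEstimate:
    peak_depth: int
    total_kmers_used: int
    genome_size: float          # bp, real-valued division
    excluded_low_depth: int     # depth cutoff applied (0 = none)


def _smooth(counts: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge bins kept as-is."""
    if len(counts) < 3:
        return counts.astype(float)
    out = counts.astype(float).copy()
    out[1:-1] = (counts[:-2] + counts[1:-1] + counts[2:]) / 3.0
    return out


def find_main_peak(hist: KmerHistogram, smooth: bool = False) -> tuple[int, int]:
    """Locate the error-tail valley and the main coverage peak.

    Returns ``(valley_depth, peak_depth)``; ``valley_depth`` is 0 when the
    histogram has no descending error tail (e.g. a single-depth histogram).
    A monotonically decreasing histogram has no identifiable coverage peak
    and raises :class:`EstimationError`.
    """
    depth = hist.depth
    count = _smooth(hist.count) if smooth else hist.count.astype(float)
    n = len(depth)
    if n == 1:
        return 0, int(depth[0])
    # first local minimum: count dropped and then rises
    valley_idx = None
    for i in range(1, n - 1):
        if count[i - 1] > count[i] and count[i] < count[i + 1]:
            valley_idx = i
            break
    if valley_idx is None:
        if np.all(np.diff(count) < 0):
            raise EstimationError(
                "histogram is monotonically decreasing: no coverage peak; "
                "supply a manual low-depth cutoff"
            )
        # no error tail: the histogram rises into its peak directly
        return 0, int(depth[int(np.argmax(count))])
    after = slice(valley_idx + 1, n)
    peak_idx = valley_idx + 1 + int(np.argmax(count[after]))
    return int(depth[valley_idx]), int(depth[peak_idx])


def estimate_genome_size(
    hist: KmerHistogram,
    low_depth_cutoff: int | str = "auto",
    smooth: bool = False,
) -> GenomeSizeEstimate:
    """Estimate genome size as total k-mer instances over the peak depth.

    ``low_depth_cutoff="auto"`` uses the detected valley depth; an integer
    cutoff excludes all depths <= cutoff from the instance total (and from
    peak search). A cutoff at or above the peak leaves nothing to estimate
    from and raises :class:`EstimationError`.
    """
    if low_depth_cutoff == "auto":
        cutoff, peak_depth = find_main_peak(hist, smooth=smooth)
    else:
        cutoff = int(low_depth_cutoff)
        mask = hist.depth > cutoff
        if not np.any(mask):
            raise EstimationError(f"cutoff {cutoff} excludes the whole histogram")
        counts = _smooth(hist.count) if smooth else hist.count.astype(float)
        sub_idx = np.flatnonzero(mask)
        peak_depth = int(hist.depth[sub_idx[np.argmax(counts[sub_idx])]])
        auto_valley, auto_peak = 0, None
        try:
            auto_valley, auto_peak = find_main_peak(hist, smooth=smooth)
        except EstimationError:
            pass
        if auto_peak is not None and cutoff >= auto_peak:
            raise EstimationError(
                f"low-depth cutoff {cutoff} is at or above the coverage peak "
                f"({auto_peak}); estimate would be meaningless"
            )
    keep = hist.depth > cutoff
    total = int(np.sum(hist.depth[keep] * hist.count[keep]))
    if total == 0:
        raise EstimationError("no k-mer instances above the cutoff")
    return GenomeSizeEstimate(
        peak_depth=peak_depth,
        total_kmers_used=total,
        genome_size=total / peak_depth,
        excluded_low_depth=cutoff,
    )
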