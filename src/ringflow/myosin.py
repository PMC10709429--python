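"""Total ring myosin, enrichment rate and kymographs.

The total ring signal at each time point is measured on *raw* frames
using two masks derived from the ring segmentation: mask 1 is the
segmentation dilated four times and mask 2 the segmentation eroded four
times (3x3 cross structuring element per iteration); the ring signal is
the summed intensity inside mask 1 minus that inside mask 2, so the
cytoplasmic contribution interior to the ring cancels.

The myosin enrichment rate is the mean slope of lines connecting local
minima to subsequent local maxima of the (smoothed) total-signal series
after cytokinesis onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "IntensitySeries",
    "ring_intensity_series",
    "enrichment_rate",
    "EnrichmentResult",
    "kymograph",
]

CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross


@dataclass
class IntensitySeries:
    """Per-frame total ring signal (background-uncorrected raw sums)."""

    t: np.ndarray
    total: np.ndarray          # M(t), AU
    area1: np.ndarray          # |mask1|, px
    area2: np.ndarray          # |mask2|, px
    erosion_empty: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.erosion_empty is None:
            self.erosion_empty = np.zeros(self.t.shape, dtype=bool)


def ring_intensity_series(raw_stack: np.ndarray, mask_stack: np.ndarray,
                          times: np.ndarray, *, n_dilate: int = 4,
                          n_erode: int = 4) -> IntensitySeries:
    """Total ring myosin signal per frame.

    ``M(t) = sum(raw in mask1) - sum(raw in mask2)`` with mask1/mask2 the
    n-fold dilation/erosion of the segmentation mask. A frame whose
    erosion annihilates the mask contributes the mask-1 sum alone and is
    flagged; a frame with an empty segmentation mask is NaN.
    """
    raw_stack = np.asarray(raw_stack, dtype=float)
    mask_stack = np.asarray(mask_stack, dtype=bool)
    if raw_stack.shape != mask_stack.shape:
        raise ValueError("raw and mask stacks must have the same shape")
    n = len(raw_stack)
    total = np.full(n, np.nan)
    area1 = np.zeros(n)
    area2 = np.zeros(n)
    empty_flags = np.zeros(n, dtype=bool)
    for k in range(n):
        mask = mask_stack[k]
        if not mask.any():
            continue
        mask1 = ndimage.binary_dilation(mask, CROSS, iterations=n_dilate)
        mask2 = ndimage.binary_erosion(mask, CROSS, iterations=n_erode)
        area1[k] = mask1.sum()
        area2[k] = mask2.sum()
        if mask2.any():
            total[k] = raw_stack[k][mask1].sum() - raw_stack[k][mask2].sum()
        else:
            total[k] = raw_stack[k][mask1].sum()
            empty_flags[k] = True
    return IntensitySeries(t=np.asarray(times, dtype=float), total=total,
                           area1=area1, area2=area2, erosion_empty=empty_flags)


@dataclass
class EnrichmentResult:
    rate: float                          # mean min->max slope, AU/s
    pairs: list = field(default_factory=list)  # (t_min, t_max, slope)
    fallback: bool = False               # least-squares fallback used


def _extremum_indices(y: np.ndarray, prominence: float):
    """Alternating minima/maxima, endpoints included where natural."""
    maxima, _ = signal.find_peaks(y, prominence=prominence)
    minima, _ = signal.find_peaks(-y, prominence=prominence)
    labelled = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    # the series start acts as a minimum if the first labelled extremum is
    # a maximum (or none exist but the series rises); the end acts as a
    # maximum symmetrically
    if not labelled:
        if y[-1] > y[0]:
            labelled = [(0, "min"), (len(y) - 1, "max")]
        return labelled
    if labelled[0][1] == "max" and labelled[0][0] > 0:
        labelled.insert(0, (0, "min"))
    if labelled[-1][1] == "min" and labelled[-1][0] < len(y) - 1:
        labelled.append((len(y) - 1, "max"))
    return labelled


def enrichment_rate(series: IntensitySeries, t_onset: float, *,
                    smooth_window: int = 3,
                    prominence_frac: float = 0.02) -> EnrichmentResult:
    """Mean slope of rising min->max segments after cytokinesis onset.

    Extrema are detected on the moving-average-smoothed series with a
    prominence threshold of ``prominence_frac`` of the series range;
    slopes are computed from the raw values at the extremum frames. If
    no rising pair exists the least-squares slope of the whole post-onset
    series is returned, flagged as a fallback.
    """
    sel = (series.t >= t_onset) & np.isfinite(series.total)
    if np.count_nonzero(sel) < 2:
        raise ValueError("fewer than 2 finite frames after onset")
    t, y = series.t[sel], series.total[sel]
    ys = ndimage.uniform_filter1d(y, smooth_window, mode="nearest") \
        if smooth_window > 1 else y
    rng = np.ptp(ys)
    extrema = _extremum_indices(ys, prominence=prominence_frac * rng) \
        if rng > 0 else []
    pairs = []
    for (i0, kind0), (i1, kind1) in zip(extrema[:-1], extrema[1:]):
        if kind0 == "min" and kind1 == "max" and y[i1] > y[i0]:
            slope = (y[i1] - y[i0]) / (t[i1] - t[i0])
            pairs.append((float(t[i0]), float(t[i1]), float(slope)))
    if pairs:
        return EnrichmentResult(rate=float(np.mean([p[2] for p in pairs])),
                                pairs=pairs)
    slope = stats.linregress(t, y).slope
    return EnrichmentResult(rate=float(slope), fallback=True)


def kymograph(stack: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Space-time image from a rectangular region of a stack.

    ``rect = (x, y, w, h)`` in pixels; each frame's region is averaged
    across its short axis to a 1D profile and profiles are stacked as
    rows in time order. Raises if the rectangle leaves the frame.
    """
    x, y, w, h = rect
    n, rows, cols = np.asarray(stack).shape
    if w <= 0 or h <= 0:
        raise ValueError("rectangle must have positive size")
    if x < 0 or y < 0 or x + w > cols or y + h > rows:
        raise ValueError("rectangle outside image bounds")
    region = np.asarray(stack, dtype=float)[:, y:y + h, x:x + w]
    # average across the short axis so the profile runs along the long one
    axis = 1 if h <= w else 2
    return region.mean(axis=axis)
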