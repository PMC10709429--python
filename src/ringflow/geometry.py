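"""Contractile-ring segmentation and closure metrics.

Per-frame segmentation of the en-face ring view yields ring radius,
centroid and orientation; from those the dimensionless closure metrics
follow, with ``R0`` the radius and ``Q_t`` the centroid displacement of
the first valid frame:

    R_closure(t) = (R0 - R_t) / R0
    E(t)         = Q_t / R0
    L_lead(t)    = (R0 + Q_t - R_t) / (2 R0)
    L_lag(t)     = (R0 - Q_t - R_t) / (2 R0)

``L_lead + L_lag == R_closure`` holds identically (pure algebra), and
``E <= R_closure`` whenever ``L_lag >= 0``.

Summary statistics: closure velocity ``v`` is the least-squares slope of
``R_closure`` over its linear range (default 0.2 < R_closure < 0.7);
cytokinesis onset ``t0`` extrapolates an initial linear part of the
closure curve to zero; the time lag ``dt`` is the delay of the lagging
edge reaching 10% ingression relative to the leading edge, and the
normalized lag is ``dt_n = v * dt``. The normalized time axis is
``t_n = (t - t0) * v``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure, morphology

__all__ = [
    "RingFrame",
    "RingSeries",
    "ClosureSummary",
    "segment_ring",
    "segment_stack",
    "series_from_truth",
    "closure_metrics",
    "compute_metrics",
    "align_series",
    "estimate_onset",
    "summarize_closure",
    "edge_velocity",
    "min_enclosing_circle",
]


@dataclass
class RingFrame:
    """Per-frame ring measurement (micrometre units)."""

    t: float
    radius: float
    centroid: tuple[float, float]   # (x, y) um
    angle: float = 0.0              # orientation, degrees
    area: float = 0.0               # um^2
    valid: bool = True


@dataclass
class RingSeries:
    """Ordered ring measurements plus derived closure-metric arrays."""

    t: np.ndarray
    radius: np.ndarray
    centroid: np.ndarray            # (n, 2) um
    valid: np.ndarray
    angle: np.ndarray = None        # type: ignore[assignment]
    area: np.ndarray = None         # type: ignore[assignment]
    R0: float = np.nan
    Q: np.ndarray = None            # type: ignore[assignment]
    metrics: dict = field(default_factory=dict)
    alignment_offset: float = np.nan

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.angle is None:
            self.angle = np.zeros_like(self.t)
        if self.area is None:
            self.area = np.full_like(self.t, np.nan)

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_frames(cls, frames: list[RingFrame]) -> "RingSeries":
        return cls(
            t=[f.t for f in frames],
            radius=[f.radius for f in frames],
            centroid=[f.centroid for f in frames],
            valid=[f.valid for f in frames],
            angle=np.array([f.angle for f in frames]),
            area=np.array([f.area for f in frames]),
        )


@dataclass
class ClosureSummary:
    """Scalar summary of one ring-closure series."""

    onset: float                    # t0, s
    velocity: float                 # v, closure fraction per s
    time_lag: float                 # dt, s (nan if censored)
    time_lag_censored: bool
    normalized_time_lag: float      # dt_n = v * dt
    peak_eccentricity: float
    lagging_furrow_onset: float     # first t with L_lag > 0.02
    t_normalized: np.ndarray = None  # type: ignore[assignment]


def _ellipse_radius(region) -> float:
    return (region.axis_major_length + region.axis_minor_length) / 4.0


def segment_ring(image: np.ndarray, pixel_size: float, *,
                 blur_sigma: float = 1.0, threshold: str = "otsu",
                 min_area_um2: float = 1.0, t: float = 0.0,
                 prev_centroid: tuple[float, float] | None = None):
    """Segment one en-face ring frame.

    Pipeline: Gaussian smoothing -> intensity threshold (Otsu by
    default) -> morphological closing -> hole filling -> largest
    connected component -> ellipse fit. The reported radius is the mean
    of the ellipse fits of the filled outline and of the interior hole
    (the mid-line of the annulus shell), falling back to the filled-region
    fit once the hole has closed; the centroid is the filled-region
    centroid.

    Returns ``(mask, RingFrame)``; a frame with no component above
    ``min_area_um2`` comes back with ``valid=False`` rather than raising.
    Among equally plausible components the one nearest ``prev_centroid``
    (or the image centre) wins.
    """
    image = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, blur_sigma) if blur_sigma > 0 else image
    empty = np.zeros(image.shape, dtype=bool)
    invalid = RingFrame(t=t, radius=np.nan, centroid=(np.nan, np.nan), valid=False)
    if not np.isfinite(smoothed).all() or smoothed.max() <= smoothed.min():
        return empty, invalid
    if threshold == "otsu":
        thr = filters.threshold_otsu(smoothed)
    elif threshold == "half-max":
        thr = (smoothed.max() + smoothed.min()) / 2.0
    else:
        raise ValueError(f"unknown threshold method {threshold!r}")
    binary = smoothed > thr
    binary = morphology.closing(binary, morphology.disk(2))
    filled = ndimage.binary_fill_holes(binary)
    labels = measure.label(filled)
    regions = measure.regionprops(labels)
    min_area_px = min_area_um2 / pixel_size ** 2
    regions = [r for r in regions if r.area >= min_area_px]
    if not regions:
        return empty, invalid
    if prev_centroid is None:
        ref = (image.shape[0] / 2.0, image.shape[1] / 2.0)
    else:
        ref = (prev_centroid[1] / pixel_size, prev_centroid[0] / pixel_size)
    biggest = max(r.area for r in regions)
    candidates = [r for r in regions if r.area >= 0.9 * biggest]
    region = min(candidates, key=lambda r: (r.centroid[0] - ref[0]) ** 2
                 + (r.centroid[1] - ref[1]) ** 2)
    comp = labels == region.label

    r_out = _ellipse_radius(region)
    hole = comp & ~binary
    hole_regions = measure.regionprops(measure.label(hole))
    if hole_regions:
        inner = max(hole_regions, key=lambda r: r.area)
        # require a genuine interior hole, not threshold speckle
        if inner.area >= 0.05 * region.area:
            r_in = _ellipse_radius(inner)
            radius_px = (r_out + r_in) / 2.0
        else:
            radius_px = r_out
    else:
        radius_px = r_out
    cy, cx = region.centroid
    frame = RingFrame(
        t=t,
        radius=radius_px * pixel_size,
        centroid=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
        angle=float(np.degrees(region.orientation)),
        area=float(region.area) * pixel_size ** 2,
        valid=True,
    )
    return comp, frame


def segment_stack(stack: np.ndarray, pixel_size: float, frame_interval: float,
                  **kwargs) -> tuple[np.ndarray, RingSeries]:
    """Segment every frame of an en-face stack, tracking the centroid.

    Returns ``(masks, RingSeries)`` with masks shaped like the stack.
    """
    frames: list[RingFrame] = []
    masks = np.zeros(stack.shape, dtype=bool)
    prev = None
    for k, img in enumerate(stack):
        mask, fr = segment_ring(img, pixel_size, t=k * frame_interval,
                                prev_centroid=prev, **kwargs)
        masks[k] = mask
        frames.append(fr)
        if fr.valid:
            prev = fr.centroid
    return masks, RingSeries.from_frames(frames)


def series_from_truth(truth) -> RingSeries:
    """Build a RingSeries directly from scene ground truth (no images)."""
    return RingSeries(
        t=truth.t,
        radius=truth.radius,
        centroid=truth.center,
        valid=np.ones(len(truth.t), dtype=bool),
    )


def closure_metrics(R0: float, R_t, Q_t) -> dict[str, np.ndarray]:
    """Closure metrics from raw geometry (pure algebra).

    ``R0`` initial radius, ``R_t`` current radius, ``Q_t`` centroid
    displacement from the initial centroid (all um, arrays allowed).
    """
    R = np.asarray(R_t, dtype=float)
    Q = np.asarray(Q_t, dtype=float)
    return {
        "R_closure": (R0 - R) / R0,
        "E": Q / R0,
        "L_lead": (R0 + Q - R) / (2 * R0),
        "L_lag": (R0 - Q - R) / (2 * R0),
    }


def compute_metrics(series: RingSeries) -> dict[str, np.ndarray]:
    """Compute closure metrics in place and return them.

    ``R0`` and the reference centroid come from the first valid frame;
    invalid frames carry NaN metrics.
    """
    valid_idx = np.flatnonzero(series.valid)
    if valid_idx.size == 0:
        raise ValueError("no valid frame to define R0")
    first = valid_idx[0]
    R0 = series.radius[first]
    if not R0 > 0:
        raise ValueError("R0 of first valid frame must be positive")
    Q = np.linalg.norm(series.centroid - series.centroid[first], axis=1)
    Q = np.where(series.valid, Q, np.nan)
    R = np.where(series.valid, series.radius, np.nan)
    series.R0 = R0
    series.Q = Q
    series.metrics = closure_metrics(R0, R, Q)
    return series.metrics


def align_series(series: RingSeries, level: float = 0.10) -> RingSeries:
    """Set the alignment offset to the first time R_closure exceeds ``level``.

    Strict exceedance at frame resolution; metric arrays are unchanged.
    Raises if the level is never exceeded, reporting the maximum reached.
    """
    if not series.metrics:
        compute_metrics(series)
    rc = series.metrics["R_closure"]
    above = np.flatnonzero(rc > level)
    if above.size == 0:
        raise ValueError(
            f"closure never exceeds {level}; max reached {np.nanmax(rc):.4f}")
    series.alignment_offset = float(series.t[above[0]])
    return series


def estimate_onset(series: RingSeries,
                   fit_window: tuple[float, float] = (0.05, 0.25)) -> float:
    """Extrapolate the initial linear part of the closure curve to zero.

    Least-squares line through frames whose closure lies inside
    ``fit_window``; onset ``t0 = -intercept / slope``. Requires at least
    3 frames in the window and a positive slope.
    """
    if not series.metrics:
        compute_metrics(series)
    rc = series.metrics["R_closure"]
    sel = (rc >= fit_window[0]) & (rc <= fit_window[1]) & series.valid
    if np.count_nonzero(sel) < 3:
        raise ValueError(f"fewer than 3 frames with closure in {fit_window}")
    res = stats.linregress(series.t[sel], rc[sel])
    if res.slope <= 0:
        raise ValueError(f"non-positive closure slope {res.slope:.3g} in window")
    return float(-res.intercept / res.slope)


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float,
                    interpolate: bool) -> float:
    """First time y >= level (frame-level, or sub-frame linear interp)."""
    idx = np.flatnonzero(y >= level)
    if idx.size == 0:
        return np.nan
    i = idx[0]
    if not interpolate or i == 0 or not np.isfinite(y[i - 1]):
        return float(t[i])
    y0, y1 = y[i - 1], y[i]
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def summarize_closure(series: RingSeries, *,
                      onset_window: tuple[float, float] = (0.05, 0.25),
                      velocity_window: tuple[float, float] = (0.2, 0.7),
                      lag_level: float = 0.10,
                      furrow_onset_level: float = 0.02,
                      interpolate: bool = False) -> ClosureSummary:
    """Summarise a closure series into its scalar descriptors.

    * velocity ``v``: least-squares slope of R_closure over frames with
      ``velocity_window[0] < R_closure < velocity_window[1]``;
    * time lag ``dt``: lagging-edge minus leading-edge first crossing of
      ``lag_level`` ingression (frame-level by default); if the lagging
      edge never reaches the level before the series ends the lag is
      censored (NaN with flag);
    * peak eccentricity: max E over valid frames;
    * lagging-furrow onset: first t with ``L_lag > furrow_onset_level``.
    """
    if not series.metrics:
        compute_metrics(series)
    m = series.metrics
    t0 = estimate_onset(series, onset_window)
    rc = m["R_closure"]
    sel = (rc > velocity_window[0]) & (rc < velocity_window[1]) & series.valid
    if np.count_nonzero(sel) < 2:
        raise ValueError("fewer than 2 frames in the velocity window")
    v = float(stats.linregress(series.t[sel], rc[sel]).slope)

    t_lead = _first_crossing(series.t, m["L_lead"], lag_level, interpolate)
    t_lag = _first_crossing(series.t, m["L_lag"], lag_level, interpolate)
    censored = not np.isfinite(t_lag)
    dt = np.nan if censored else t_lag - t_lead
    dtn = np.nan if censored else v * dt

    onset_idx = np.flatnonzero(m["L_lag"] > furrow_onset_level)
    lag_furrow = float(series.t[onset_idx[0]]) if onset_idx.size else np.nan

    return ClosureSummary(
        onset=t0,
        velocity=v,
        time_lag=float(dt),
        time_lag_censored=censored,
        normalized_time_lag=float(dtn),
        peak_eccentricity=float(np.nanmax(m["E"])),
        lagging_furrow_onset=lag_furrow,
        t_normalized=(series.t - t0) * v,
    )


def edge_velocity(series: RingSeries, smooth_window: int = 3
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame leading/lagging edge ingression speeds (um/s).

    The edge position is reconstructed as ``2 R0 * L_edge(t)`` um of
    ingressed distance; velocity is the centred finite difference of the
    moving-average-smoothed position. Positive = ingressing.
    """
    if not series.metrics:
        compute_metrics(series)
    if len(series) < smooth_window:
        raise ValueError("series shorter than smoothing window")

    def _vel(L: np.ndarray) -> np.ndarray:
        x = 2 * series.R0 * L
        if smooth_window > 1:
            x = ndimage.uniform_filter1d(x, smooth_window, mode="nearest")
        return np.gradient(x, series.t)

    return _vel(series.metrics["L_lead"]), _vel(series.metrics["L_lag"])


# ---------------------------------------------------------------------------
# smallest enclosing circle (exact, Welzl-style)

def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.linalg.norm(a - c))


def _circle_three(a, b, c):
    """Circumcircle of three points; None if (near-)collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(np.abs([ax, ay, bx, by, cx, cy]).max(), 1.0)
    if abs(d) < 1e-12 * scale * scale:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _in_circle(p, circle, eps=1e-9) -> bool:
    center, r = circle
    return np.linalg.norm(p - center) <= r * (1 + eps) + eps


def _trivial_circle(boundary):
    if not boundary:
        return np.zeros(2), 0.0
    if len(boundary) == 1:
        return boundary[0].copy(), 0.0
    if len(boundary) == 2:
        return _circle_two(boundary[0], boundary[1])
    c = _circle_three(*boundary)
    if c is not None:
        return c
    # collinear: circle through the extreme pair
    best = None
    for p, q in itertools.combinations(boundary, 2):
        cand = _circle_two(p, q)
        if best is None or cand[1] > best[1]:
            best = cand
    return best


def min_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing circle of >= 3 planar points (um).

    Welzl's move-to-front algorithm with a deterministic seeded shuffle;
    collinear inputs reduce to the circle through the extreme pair.
    Returns ``(center, radius)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 planar points")
    order = np.random.default_rng(0).permutation(len(pts))
    shuffled = [pts[i] for i in order]

    # iterative formulation (three nested passes) to avoid deep recursion
    circle = _trivial_circle([])
    for i in range(len(shuffled)):
        if _in_circle(shuffled[i], circle):
            continue
        circle = _trivial_circle([shuffled[i]])
        for j in range(i):
            if _in_circle(shuffled[j], circle):
                continue
            circle = _circle_two(shuffled[i], shuffled[j])
            for k in range(j):
                if not _in_circle(shuffled[k], circle):
                    circle = _trivial_circle([shuffled[i], shuffled[j],
                                              shuffled[k]])
    center, radius = circle
    return np.asarray(center), float(radius)
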