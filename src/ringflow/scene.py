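"""Synthetic 4D scenes of asymmetric contractile-ring closure.

This module generates ground-truth kinematics and rendered fluorescence
time-lapse stacks that emulate the statistical structure the analysis
pipeline assumes:

* a *ring en-face view*: a bright annulus whose radius shrinks and whose
  centroid drifts along the A-P (column) axis, the signature of
  asymmetric (unilateral) closure;
* a *cortex surface view*: punctate myosin foci advected by a prescribed
  cortical flow field (a ring-directed component toward the furrow plus a
  circumferential sink that compresses the cortex toward the equator).

Edge kinematics are piecewise-linear ramps: each furrow edge is
stationary until its onset time and then ingresses at constant speed.
The leading edge sits at the lower column coordinate. From the two edge
positions the ring radius and centre follow exactly, and so do the
closure metrics (closure fraction, eccentricity, per-edge ingression)
used as ground truth in recovery tests.

All randomness is driven by the config seed; identical configs produce
bit-identical truth and images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .fields import FlowField

__all__ = [
    "FlowParams",
    "SceneConfig",
    "SceneTruth",
    "build_scene",
    "render_ring_view",
    "render_cortex_view",
    "render_ring_stack",
    "render_cortex_stack",
    "analytic_flow_field",
    "random_scene_configs",
    "write_scene",
]


@dataclass
class FlowParams:
    """Parameters of the prescribed cortex flow field.

    The field has two components, each switched on at its own onset time:

    * ring-directed: uniform flow ``u = ring_amplitude`` toward the
      furrow along +x (um/s), emulating pole-to-furrow cortical flow;
    * circumferential sink: ``v = -circ_rate * (y - y_mid)`` (um/s),
      a linear sink toward the equatorial mid-line whose exact
      circumferential convergence is ``circ_rate`` (1/s) everywhere.
    """

    ring_amplitude: float = 0.08
    ring_onset: float = 0.0
    circ_rate: float = 0.005
    circ_onset: float = 0.0

    def velocity(self, x, y, t, y_mid):
        """Evaluate the flow at positions (x, y) um and time t s."""
        u = np.where(t >= self.ring_onset, self.ring_amplitude, 0.0)
        u = np.broadcast_to(u, np.shape(x)).astype(float)
        v = np.where(t >= self.circ_onset, -self.circ_rate * (np.asarray(y) - y_mid), 0.0)
        return u, np.asarray(v, dtype=float)


@dataclass
class SceneConfig:
    """Full parameterisation of a synthetic scene.

    Units: micrometres, seconds, arbitrary intensity units (AU).
    ``ring_thickness`` is the Gaussian sigma of the annulus radial
    cross-section. ``lag_edge_speed`` defaults to ``edge_speed``;
    ``lag_onset`` may be ``inf`` for a fully unilateral scene.
    """

    R0: float = 10.0
    frame_interval: float = 5.6
    n_frames: int = 40
    pixel_size: float = 0.18
    image_shape: tuple[int, int] = (160, 160)
    lead_onset: float = 0.0
    lag_onset: float = 100.0
    edge_speed: float = 0.05
    lag_edge_speed: float | None = None
    ring_thickness: float = 0.4
    ring_intensity: float = 100.0
    lag_intensity_factor: float = 1.0
    n_foci: int = 150
    foci_sigma: float = 0.3
    foci_intensity: float = 100.0
    flow_params: FlowParams = field(default_factory=FlowParams)
    noise_sigma: float = 5.0
    background: float = 10.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_edge_speed is None:
            self.lag_edge_speed = self.edge_speed
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.lead_onset < 0 or self.lag_onset < self.lead_onset:
            raise ValueError("onsets must satisfy 0 <= lead_onset <= lag_onset")
        if self.edge_speed < 0 or self.lag_edge_speed < 0:
            raise ValueError("edge speeds must be non-negative")
        # the rendered ring must never leave the frame: the initial annulus
        # is the largest structure and the centre only drifts inward
        half_w = self.image_shape[1] * self.pixel_size / 2.0
        half_h = self.image_shape[0] * self.pixel_size / 2.0
        margin = 3.0 * self.ring_thickness
        if self.R0 + margin > min(half_w, half_h):
            raise ValueError(
                f"ring of radius {self.R0} um does not fit the "
                f"{self.image_shape} px frame at {self.pixel_size} um/px"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the frame in micrometres."""
        return (self.image_shape[1] * self.pixel_size,
                self.image_shape[0] * self.pixel_size)


@dataclass
class SceneTruth:
    """Exact ground-truth kinematics of a built scene.

    ``x_lead``/``x_lag`` are furrow-edge positions along the column (A-P)
    axis in micrometres; radius and centre are derived from them:
    ``radius = (x_lag - x_lead) / 2`` and the centre is the edge
    midpoint. ``foci`` holds per-frame focus positions (um) advected
    through the prescribed flow by explicit per-frame Euler steps;
    ``foci_in_bounds`` flags foci still inside the frame.
    """

    config: SceneConfig
    t: np.ndarray
    x_lead: np.ndarray
    x_lag: np.ndarray
    center: np.ndarray          # (n, 2) -> (x, y) um
    radius: np.ndarray
    foci: np.ndarray            # (n, n_foci, 2) -> (x, y) um
    foci_in_bounds: np.ndarray  # (n, n_foci) bool
    truncated: bool = False

    def metrics(self) -> dict[str, np.ndarray]:
        """Closure metrics computed analytically from the truth.

        Returns ``R_closure``, ``E``, ``L_lead`` and ``L_lag`` arrays;
        by construction ``L_lead + L_lag == R_closure`` exactly and
        ``0 <= E <= R_closure`` whenever ``L_lag >= 0``.
        """
        R0 = self.radius[0]
        Q = np.linalg.norm(self.center - self.center[0], axis=1)
        R_closure = (R0 - self.radius) / R0
        E = Q / R0
        L_lead = (R0 + Q - self.radius) / (2 * R0)
        L_lag = (R0 - Q - self.radius) / (2 * R0)
        return {"R_closure": R_closure, "E": E, "L_lead": L_lead, "L_lag": L_lag}

    def flow_velocity(self, x, y, t):
        """Prescribed cortex flow at (x, y) um, time t s."""
        _, height = self.config.extent_um
        return self.config.flow_params.velocity(x, y, t, y_mid=height / 2.0)


def _edge_position(t: np.ndarray, start: float, onset: float, speed: float,
                   direction: float) -> np.ndarray:
    ramp = np.clip(t - onset, 0.0, None)
    ramp = np.where(np.isfinite(ramp), ramp, 0.0)
    return start + direction * speed * ramp


def build_scene(config: SceneConfig) -> SceneTruth:
    """Build the exact ground-truth kinematics for ``config``.

    Edge positions are piecewise-linear ramps (stationary until the
    edge's onset, then ingressing at its speed). If the two edges would
    cross before ``n_frames`` (ring radius < 0) the series is truncated
    at closure and the truth flagged ``truncated``.
    """
    t = config.times
    width, height = config.extent_um
    cx0, cy0 = width / 2.0, height / 2.0
    x_lead = _edge_position(t, cx0 - config.R0, config.lead_onset,
                            config.edge_speed, +1.0)
    x_lag = _edge_position(t, cx0 + config.R0, config.lag_onset,
                           config.lag_edge_speed, -1.0)
    radius = (x_lag - x_lead) / 2.0
    truncated = False
    if np.any(radius < 0):
        last = int(np.argmax(radius < 0))
        t, x_lead, x_lag, radius = t[:last], x_lead[:last], x_lag[:last], radius[:last]
        truncated = True
    center = np.column_stack([(x_lead + x_lag) / 2.0,
                              np.full(t.shape, cy0)])

    # foci: seeded initial positions, then explicit Euler advection
    rng = np.random.default_rng([config.seed, 2])
    margin = 3.0 * config.foci_sigma
    init = np.column_stack([
        rng.uniform(margin, width - margin, config.n_foci),
        rng.uniform(margin, height - margin, config.n_foci),
    ])
    foci = np.empty((len(t), config.n_foci, 2))
    foci[0] = init
    for k in range(1, len(t)):
        x, y = foci[k - 1, :, 0], foci[k - 1, :, 1]
        u, v = config.flow_params.velocity(x, y, t[k - 1], y_mid=height / 2.0)
        foci[k, :, 0] = x + u * config.frame_interval
        foci[k, :, 1] = y + v * config.frame_interval
    in_bounds = ((foci[..., 0] >= 0) & (foci[..., 0] <= width)
                 & (foci[..., 1] >= 0) & (foci[..., 1] <= height))
    return SceneTruth(config=config, t=t, x_lead=x_lead, x_lag=x_lag,
                      center=center, radius=radius, foci=foci,
                      foci_in_bounds=in_bounds, truncated=truncated)


def _pixel_grid(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = config.image_shape
    x = (np.arange(cols) + 0.5) * config.pixel_size
    y = (np.arange(rows) + 0.5) * config.pixel_size
    return np.meshgrid(x, y)


def _add_noise(signal: np.ndarray, config: SceneConfig, frame: int,
               stream: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, stream, frame])
    out = signal
    if config.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if config.noise_sigma > 0:
        out = out + rng.normal(0.0, config.noise_sigma, size=out.shape)
    return out


def render_ring_view(truth: SceneTruth, frame: int,
                     config: SceneConfig | None = None) -> np.ndarray:
    """Render the en-face ring view at ``frame`` (float AU image).

    The ring is an annulus with a Gaussian radial cross-section
    (sigma = ``ring_thickness``); when the radius has shrunk to zero the
    same expression degenerates to a single Gaussian blob at the centre.
    Intensity may be graded between the leading (x < centre) and lagging
    semicircles via ``lag_intensity_factor``.
    """
    config = config or truth.config
    if not 0 <= frame < len(truth.t):
        raise IndexError(f"frame {frame} outside series of {len(truth.t)}")
    X, Y = _pixel_grid(config)
    cx, cy = truth.center[frame]
    R = truth.radius[frame]
    d = np.hypot(X - cx, Y - cy)
    amp = np.where(X < cx, config.ring_intensity,
                   config.ring_intensity * config.lag_intensity_factor)
    img = amp * np.exp(-0.5 * ((d - R) / config.ring_thickness) ** 2)
    img = img + config.background
    return _add_noise(img, config, frame, stream=0)


def render_cortex_view(truth: SceneTruth, frame: int,
                       config: SceneConfig | None = None) -> np.ndarray:
    """Render the cortex surface view at ``frame`` (float AU image).

    Sum of Gaussian spots at the advected foci positions plus background
    and seeded noise. Foci advected out of the frame are dropped from
    rendering but retained in the truth with an out-of-bounds flag.
    """
    config = config or truth.config
    if not 0 <= frame < len(truth.t):
        raise IndexError(f"frame {frame} outside series of {len(truth.t)}")
    X, Y = _pixel_grid(config)
    img = np.zeros(config.image_shape, dtype=float)
    s2 = 2.0 * config.foci_sigma ** 2
    cutoff = 4.0 * config.foci_sigma
    px = config.pixel_size
    rows, cols = config.image_shape
    for (fx, fy), ok in zip(truth.foci[frame], truth.foci_in_bounds[frame]):
        if not ok:
            continue
        # evaluate each spot only on its local patch for speed
        c0 = max(int((fx - cutoff) / px), 0)
        c1 = min(int((fx + cutoff) / px) + 2, cols)
        r0 = max(int((fy - cutoff) / px), 0)
        r1 = min(int((fy + cutoff) / px) + 2, rows)
        if c0 >= c1 or r0 >= r1:
            continue
        patch = np.exp(-((X[r0:r1, c0:c1] - fx) ** 2
                         + (Y[r0:r1, c0:c1] - fy) ** 2) / s2)
        img[r0:r1, c0:c1] += config.foci_intensity * patch
    img = img + config.background
    return _add_noise(img, config, frame, stream=1)


def render_ring_stack(truth: SceneTruth) -> np.ndarray:
    """Render every frame of the en-face ring view, shape (n, rows, cols)."""
    return np.stack([render_ring_view(truth, k) for k in range(len(truth.t))])


def render_cortex_stack(truth: SceneTruth) -> np.ndarray:
    """Render every frame of the cortex surface view."""
    return np.stack([render_cortex_view(truth, k) for k in range(len(truth.t))])


def analytic_flow_field(kind: str, params: dict, *, shape: tuple[int, int],
                        spacing: float, origin: tuple[float, float] = (0.0, 0.0),
                        t: float = 0.0):
    """Sample a closed-form flow field and its exact convergence.

    Parameters
    ----------
    kind : {"uniform", "linear_sink", "ring_directed_ramp"}
        * ``uniform``: u = params["u0"], v = params["v0"]; convergence 0.
        * ``linear_sink``: u = -k1 (x - x0), v = -k2 (y - y0); A-P
          convergence ``p = k1`` and circumferential ``q = k2``
          everywhere (params: k1, k2, x0, y0; defaults 0).
        * ``ring_directed_ramp``: u = A * clip((xf - x) / L, 0, 1),
          v = 0 -- flow toward a furrow at x = xf decaying linearly to
          zero over length L; p = A / L within the ramp, 0 outside
          (params: amplitude, furrow_x, ramp_length).
    shape, spacing, origin
        Grid specification (rows, cols), spacing in um, origin um.

    Returns
    -------
    (FlowField, p_exact, q_exact)
        The sampled field and its analytic convergence on the same grid.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    n_rows, n_cols = shape
    x = origin[0] + np.arange(n_cols) * spacing
    y = origin[1] + np.arange(n_rows) * spacing
    X, Y = np.meshgrid(x, y)
    if kind == "uniform":
        u = np.full(shape, float(params.get("u0", 0.0)))
        v = np.full(shape, float(params.get("v0", 0.0)))
        p = np.zeros(shape)
        q = np.zeros(shape)
    elif kind == "linear_sink":
        k1 = float(params.get("k1", 0.0))
        k2 = float(params.get("k2", 0.0))
        u = -k1 * (X - float(params.get("x0", 0.0)))
        v = -k2 * (Y - float(params.get("y0", 0.0)))
        p = np.full(shape, k1)
        q = np.full(shape, k2)
    elif kind == "ring_directed_ramp":
        A = float(params["amplitude"])
        xf = float(params["furrow_x"])
        L = float(params["ramp_length"])
        frac = np.clip((xf - X) / L, 0.0, 1.0)
        u = A * frac
        v = np.zeros(shape)
        p = np.where((X > xf - L) & (X < xf), A / L, 0.0)
        q = np.zeros(shape)
    else:
        raise ValueError(f"unknown analytic field kind: {kind!r}")
    return FlowField(u=u, v=v, spacing=spacing, origin=origin, t=t), p, q


def random_scene_configs(n: int, seed: int, symmetric_every: int = 4,
                         **overrides) -> list[SceneConfig]:
    """Draw ``n`` seeded scene configs spanning symmetric to fully
    unilateral closure.

    Every ``symmetric_every``-th config is exactly symmetric
    (``lag_onset == lead_onset``, equal speeds); the rest draw a lag
    onset in [40, 160] s and per-edge speeds in [0.04, 0.06] um/s.
    The frame count is chosen per scene so the closure fraction reaches
    ~0.8 before the series ends.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n):
        R0 = rng.uniform(8.5, 10.5)
        if i % symmetric_every == 0:
            lead_speed = lag_speed = rng.uniform(0.04, 0.06)
            lag_onset = 0.0
        else:
            lead_speed = rng.uniform(0.04, 0.06)
            lag_speed = rng.uniform(0.04, 0.06)
            lag_onset = rng.uniform(40.0, 160.0)
        # time for total ingression 1.6 R0 (closure 0.8)
        d_before = lead_speed * lag_onset
        target = 1.6 * R0
        if d_before >= target:
            t_end = target / lead_speed
        else:
            t_end = lag_onset + (target - d_before) / (lead_speed + lag_speed)
        n_frames = int(np.ceil(t_end / 5.6)) + 2
        configs.append(SceneConfig(
            R0=R0, lead_onset=0.0, lag_onset=lag_onset,
            edge_speed=lead_speed, lag_edge_speed=lag_speed,
            n_frames=n_frames, seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        ))
    return configs


def write_scene(truth: SceneTruth, outdir: str | Path) -> dict[str, Path]:
    """Write a scene to disk: 16-bit TIFF stacks, truth CSV, config JSON."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _quantize(stack: np.ndarray) -> np.ndarray:
        lo = min(0.0, float(stack.min()))
        scale = 65535.0 / max(float(stack.max()) - lo, 1e-12)
        return ((stack - lo) * scale).astype(np.uint16)

    ring = render_ring_stack(truth)
    cortex = render_cortex_stack(truth)
    paths["ring"] = outdir / "ring.tif"
    paths["cortex"] = outdir / "cortex.tif"
    tifffile.imwrite(paths["ring"], _quantize(ring),
                     photometric="minisblack")
    tifffile.imwrite(paths["cortex"], _quantize(cortex),
                     photometric="minisblack")

    m = truth.metrics()
    df = pd.DataFrame({
        "t": truth.t, "x_lead": truth.x_lead, "x_lag": truth.x_lag,
        "center_x": truth.center[:, 0], "center_y": truth.center[:, 1],
        "radius": truth.radius, **m,
    })
    paths["truth"] = outdir / "truth.csv"
    df.to_csv(paths["truth"], index=False)

    cfg = dataclasses.asdict(truth.config)
    cfg["image_shape"] = list(truth.config.image_shape)
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(json.dumps(cfg, indent=2))
    return paths
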