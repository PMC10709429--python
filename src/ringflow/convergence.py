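"""Cortical flow convergence and longitudinal strain rate.

Convergence is the negative divergence of the flow field, split per
axis: with ``u``/``v`` the A-P and circumferential velocity components
on a grid of spacing ``a`` (the PIV step size), the A-P convergence is

    p_ij = -(1/a) * (u_{i+1,j} - u_{i-1,j}) / 2      (interior)
    p_ij = -(1/a) * (u_{i+/-1,j} - u_{i,j})          (boundary)

and analogously ``q`` along the circumferential axis. Central
differences at interior points, first-order one-sided differences at the
boundary; positive values mean net influx (compression) of cortical
material. The scheme is exact for fields linear in the grid coordinate
and exactly invariant to constant-vector offsets.

The longitudinal strain rate is the fractional rate of change of the
distance between two tracked cortical foci over a fixed horizon
(default 27.9 s, five 5.6-s frames); negative = shortening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import ConvergenceField, FlowField

__all__ = [
    "convergence_field",
    "equatorial_mean",
    "relaxation_rate",
    "RelaxationResult",
    "longitudinal_strain_rate",
    "DEFAULT_STRAIN_HORIZON",
]

DEFAULT_STRAIN_HORIZON = 27.9  # s


def _axis_derivative(f: np.ndarray, axis: int) -> np.ndarray:
    """Per-index derivative: central interior, one-sided boundaries."""
    f = np.moveaxis(f, axis, 0)
    d = np.empty_like(f)
    d[1:-1] = (f[2:] - f[:-2]) / 2.0
    d[0] = f[1] - f[0]
    d[-1] = f[-1] - f[-2]
    return np.moveaxis(d, 0, axis)


def _stencil_valid(valid: np.ndarray, axis: int) -> np.ndarray:
    """A cell's derivative is valid only if every stencil cell is valid."""
    valid = np.moveaxis(valid, axis, 0)
    ok = np.empty_like(valid)
    ok[1:-1] = valid[1:-1] & valid[2:] & valid[:-2]
    ok[0] = valid[0] & valid[1]
    ok[-1] = valid[-1] & valid[-2]
    return np.moveaxis(ok, 0, axis)


def convergence_field(field: FlowField) -> ConvergenceField:
    """Axis-wise convergence of a flow field (1/s).

    Requires at least 2 cells along each differenced axis. Cells whose
    stencil touches an invalid vector are masked (no interpolation).
    """
    n_rows, n_cols = field.shape
    if n_cols < 2:
        raise ValueError("need >= 2 grid cells along the A-P axis")
    if n_rows < 2:
        raise ValueError("need >= 2 grid cells along the circumferential axis")
    a = field.spacing
    p = -_axis_derivative(field.u, axis=1) / a
    q = -_axis_derivative(field.v, axis=0) / a
    return ConvergenceField(
        p=p, q=q, spacing=a, origin=field.origin,
        valid_p=_stencil_valid(field.valid, axis=1),
        valid_q=_stencil_valid(field.valid, axis=0),
        t=field.t,
    )


def equatorial_mean(conv_fields: list[ConvergenceField], furrow_x, *,
                    furrow_y=None, block: tuple[int, int] = (6, 3)
                    ) -> dict[str, np.ndarray]:
    """Mean convergence in a block of cells centred on the furrow.

    ``block = (n_ap, n_circ)`` counts grid cells along the A-P and
    circumferential axes (default 6 x 3). Returns per-frame means of the
    ring-directed (``p``) and circumferential (``q``) convergence over
    valid cells; a block clipped by the grid edge warns, a block with no
    valid cells yields NaN.
    """
    n = len(conv_fields)
    furrow_x = np.broadcast_to(np.asarray(furrow_x, dtype=float), (n,))
    n_ap, n_circ = block
    mean_p = np.full(n, np.nan)
    mean_q = np.full(n, np.nan)
    times = np.array([c.t for c in conv_fields])
    for k, c in enumerate(conv_fields):
        n_rows, n_cols = c.shape
        jc = int(round((furrow_x[k] - c.origin[0]) / c.spacing))
        if furrow_y is None:
            ic = n_rows // 2
        else:
            ic = int(round((np.broadcast_to(furrow_y, (n,))[k]
                            - c.origin[1]) / c.spacing))
        j0, j1 = jc - n_ap // 2, jc - n_ap // 2 + n_ap
        i0, i1 = ic - n_circ // 2, ic - n_circ // 2 + n_circ
        if j0 < 0 or j1 > n_cols or i0 < 0 or i1 > n_rows:
            warnings.warn("equatorial block clipped to the grid")
        j0, j1 = max(j0, 0), min(j1, n_cols)
        i0, i1 = max(i0, 0), min(i1, n_rows)
        pv = c.valid_p[i0:i1, j0:j1]
        qv = c.valid_q[i0:i1, j0:j1]
        if pv.any():
            mean_p[k] = c.p[i0:i1, j0:j1][pv].mean()
        if qv.any():
            mean_q[k] = c.q[i0:i1, j0:j1][qv].mean()
    return {"t": times, "mean_p": mean_p, "mean_q": mean_q}


@dataclass
class RelaxationResult:
    rate: float       # (min - max) / (t_min - t_max), 1/s^2
    t_max: float
    t_min: float
    censored: bool


def relaxation_rate(t: np.ndarray, series: np.ndarray, *,
                    t_start: float, t_stop: float,
                    smooth_window: int = 3) -> RelaxationResult:
    """Slope from the convergence maximum to the subsequent minimum.

    Restricted to ``[t_start, t_stop]`` (cytokinesis onset to
    lagging-furrow onset); the series is moving-average smoothed, the
    maximum located first and the minimum searched after it. A series
    with no max-then-min pair (e.g. monotone increasing) is censored.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(series, dtype=float)
    sel = (t >= t_start) & (t <= t_stop) & np.isfinite(y)
    if np.count_nonzero(sel) < 3:
        return RelaxationResult(np.nan, np.nan, np.nan, censored=True)
    ts, ys = t[sel], y[sel]
    if smooth_window > 1:
        ys = ndimage.uniform_filter1d(ys, smooth_window, mode="nearest")
    imax = int(np.argmax(ys))
    if imax >= len(ys) - 1:
        return RelaxationResult(np.nan, float(ts[imax]), np.nan, censored=True)
    imin = imax + int(np.argmin(ys[imax:]))
    if imin == imax:
        return RelaxationResult(np.nan, float(ts[imax]), np.nan, censored=True)
    rate = (ys[imin] - ys[imax]) / (ts[imin] - ts[imax])
    return RelaxationResult(float(rate), float(ts[imax]), float(ts[imin]),
                            censored=False)


def longitudinal_strain_rate(t: np.ndarray, distance: np.ndarray, *,
                             horizon: float = DEFAULT_STRAIN_HORIZON,
                             normalize: bool = True
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Strain rate of a focus-pair distance series over a fixed horizon.

    For each sample with a partner one horizon later,

        rate(t) = (d(t + H) - d(t)) / (H * d(t))        (1/s)

    or, with ``normalize=False``, the unnormalized ``(d(t+H)-d(t))/H``
    in um/s. Negative = shortening (compression). Raises if the series
    is shorter than the horizon or if a reference distance is zero.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(distance, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("t and distance must be matching 1D arrays")
    if len(t) >= 2:
        tol = 0.5 * np.median(np.diff(t))
    else:
        tol = 0.0
    t_out, rates = [], []
    for i in range(len(t)):
        target = t[i] + horizon
        j = int(np.argmin(np.abs(t - target)))
        if abs(t[j] - target) > tol or j <= i:
            continue
        if d[i] == 0:
            raise ValueError("zero reference distance in strain-rate series")
        dt_ij = t[j] - t[i]
        rate = (d[j] - d[i]) / dt_ij
        if normalize:
            rate /= d[i]
        t_out.append(t[i])
        rates.append(rate)
    if not t_out:
        raise ValueError(
            f"track pair does not overlap for the {horizon}-s horizon")
    return np.asarray(t_out), np.asarray(rates)
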