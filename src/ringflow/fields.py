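"""Gridded vector- and scalar-field containers shared by the flow modules.

Conventions used throughout the package:

* image row  = circumferential axis (``y``),
* image column = anterior-posterior (A-P) axis (``x``), with the leading
  edge of the furrow at the lower column coordinate,
* all physical coordinates are micrometres, velocities um/s, times s.

A :class:`FlowField` lives on a regular grid whose spacing equals the PIV
step size ``a``; cell ``[i, j]`` (row, col) has its centre at
``origin + (j*a, i*a)`` in ``(x, y)`` micrometre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FlowField:
    """A 2D cortical-flow velocity field on a regular grid.

    Attributes
    ----------
    u : ndarray, shape (n_rows, n_cols)
        A-P velocity component (along columns), um/s. Positive points
        toward increasing column coordinate (posterior).
    v : ndarray, shape (n_rows, n_cols)
        Circumferential component (along rows), um/s.
    spacing : float
        Grid spacing ``a`` in micrometres (the PIV step size).
    origin : tuple of float
        ``(x, y)`` micrometre coordinates of the centre of cell [0, 0].
    valid : ndarray of bool
        Per-cell validity mask (False where estimation failed or a vector
        was rejected).
    t : float
        Time of the field in seconds.
    """

    u: np.ndarray
    v: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray = None  # type: ignore[assignment]
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.u.shape:
                raise ValueError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        """Speed |(u, v)| per cell, um/s."""
        return np.hypot(self.u, self.v)

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) micrometre coordinates of every cell centre."""
        n_rows, n_cols = self.shape
        x = self.origin[0] + np.arange(n_cols) * self.spacing
        y = self.origin[1] + np.arange(n_rows) * self.spacing
        return np.meshgrid(x, y)


@dataclass
class ConvergenceField:
    """Axis-wise flow convergence on the same grid as its source field.

    ``p`` is the A-P-axis convergence and ``q`` the circumferential-axis
    convergence, both in 1/s; positive values indicate net influx
    (compression) of cortical material. ``p + q`` equals the negative
    discrete divergence of the source field under the finite-difference
    scheme of :func:`ringflow.convergence.convergence_field`.
    """

    p: np.ndarray
    q: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    valid_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid_q: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.p.shape != self.q.shape:
            raise ValueError("p and q must have the same shape")
        if self.valid_p is None:
            self.valid_p = np.ones(self.p.shape, dtype=bool)
        if self.valid_q is None:
            self.valid_q = np.ones(self.q.shape, dtype=bool)
        self.valid_p = np.asarray(self.valid_p, dtype=bool)
        self.valid_q = np.asarray(self.valid_q, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape
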