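"""Minimal well-tempered Metadynamics on a 1D (optionally rotated) CV.

The collective variable is s(x, y) = x0 + cos(theta) (x - x0) + sin(theta)
(y - y0): the x-coordinate rotated by ``theta`` about the trajectory's
starting point, shifted so that at theta = 0 it is exactly the raw
x-coordinate and so that resetting thresholds quoted in x translate
unchanged to the rotated CV.  Rotating theta away from 0 degrades the CV
quality deliberately; the first-passage target stays the raw x criterion.

Bias is accumulated on a uniform grid, hills are Gaussians whose height is
damped well-tempered style by exp(-V(s) / (gamma_b - 1)) (energies in k_BT,
so k_BT = 1 here), and the whole table is zeroed whenever the trajectory is
reset so that every post-reset segment is a statistically fresh replica.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

__all__ = ["CVDefinition", "MetaDEngine"]


@njit(cache=True)
def _bias_value(grid, gmin, gdx, u):
    """Linearly interpolated bias at CV value u (clamped to the grid)."""
    n = grid.size
    umax = gmin + gdx * (n - 1)
    if u <= gmin:
        return grid[0]
    if u >= umax:
        return grid[n - 1]
    f = (u - gmin) / gdx
    i = int(f)
    w = f - i
    return grid[i] * (1.0 - w) + grid[i + 1] * w


@njit(cache=True)
def _bias_deriv(grid, gmin, gdx, u):
    """dV/ds: central node derivatives, linearly interpolated between nodes.

    Smooth across nodes (the force at an isolated hill centre is zero) and
    identical to a central finite difference of the interpolated bias taken
    over one grid spacing.
    """
    n = grid.size
    umax = gmin + gdx * (n - 1)
    if u <= gmin or u >= umax:
        return 0.0
    f = (u - gmin) / gdx
    i = int(f)
    w = f - i
    if i >= 1:
        d0 = (grid[i + 1] - grid[i - 1]) / (2.0 * gdx)
    else:
        d0 = (grid[1] - grid[0]) / gdx
    j = i + 1
    if j <= n - 2:
        d1 = (grid[j + 1] - grid[j - 1]) / (2.0 * gdx)
    else:
        d1 = (grid[n - 1] - grid[n - 2]) / gdx
    return (1.0 - w) * d0 + w * d1


@njit(cache=True)
def _deposit(grid, gmin, gdx, sigma, height, biasfactor, u):
    """Add one well-tempered hill centred at u; returns the damped height."""
    n = grid.size
    umax = gmin + gdx * (n - 1)
    if u < gmin:
        u = gmin
    elif u > umax:
        u = umax
    h = height * np.exp(-_bias_value(grid, gmin, gdx, u) / (biasfactor - 1.0))
    halfwidth = 6.0 * sigma
    i0 = int(math.ceil((u - halfwidth - gmin) / gdx))
    i1 = int(math.floor((u + halfwidth - gmin) / gdx))
    if i0 < 0:
        i0 = 0
    if i1 > n - 1:
        i1 = n - 1
    for i in range(i0, i1 + 1):
        d = gmin + i * gdx - u
        grid[i] += h * np.exp(-d * d / (2.0 * sigma * sigma))
    return h


@dataclasses.dataclass(frozen=True)
class CVDefinition:
    """A rotated-x collective variable, theta in degrees (0 = raw x)."""

    theta_deg: float = 0.0

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)

    def value(self, x, y):
        """Plain rotated CV, x cos(theta) + y sin(theta)."""
        return x * math.cos(self.theta_rad) + y * math.sin(self.theta_rad)

    def shifted_value(self, x, y, x0: float, y0: float):
        """Rotated CV anchored at the start point (x0, y0).

        Equals ``x0 + cos(theta) (x - x0) + sin(theta) (y - y0)``: the raw x
        coordinate at theta = 0, and offset from :meth:`value` only by a
        constant, so bias forces are identical.  Threshold lines quoted in x
        and rotated about the start point map to the same numeric threshold
        on this CV.
        """
        c, s = math.cos(self.theta_rad), math.sin(self.theta_rad)
        return x0 + c * (np.asarray(x) - x0) + s * (np.asarray(y) - y0)


class MetaDEngine:
    """Well-tempered MetaD bias table over a 1D CV.

    Parameters follow the usual conventions: deposition ``pace`` in steps,
    initial hill ``height_kt`` in k_BT, hill width ``sigma`` in Angstrom,
    dimensionless ``biasfactor`` > 1, and a uniform grid with clamping
    beyond its bounds.
    """

    def __init__(
        self,
        pace: int = 100,
        height_kt: float = 0.5,
        sigma: float = 0.15,
        biasfactor: float = 10.0,
        grid_min: float = -8.0,
        grid_max: float = 8.0,
        grid_spacing: float = 0.01,
        theta_deg: float = 0.0,
    ):
        if pace < 1:
            raise ValueError("pace must be >= 1 step")
        if biasfactor <= 1:
            raise ValueError("biasfactor must exceed 1")
        if sigma <= 0 or grid_spacing <= 0 or grid_max <= grid_min:
            raise ValueError("invalid grid or hill geometry")
        self.pace = int(pace)
        self.height_kt = float(height_kt)
        self.sigma = float(sigma)
        self.biasfactor = float(biasfactor)
        self.grid_min = float(grid_min)
        self.grid_spacing = float(grid_spacing)
        n = int(round((grid_max - grid_min) / grid_spacing)) + 1
        self.grid_max = self.grid_min + (n - 1) * self.grid_spacing
        self.cv = CVDefinition(theta_deg)
        self.grid = np.zeros(n, dtype=np.float64)
        self.n_hills = 0

    # -- operations ------------------------------------------------------
    def deposit(self, cv_value: float) -> float:
        """Deposit one hill at the CV value; returns the damped height used."""
        h = _deposit(
            self.grid, self.grid_min, self.grid_spacing,
            self.sigma, self.height_kt, self.biasfactor, float(cv_value),
        )
        self.n_hills += 1
        return h

    def bias(self, cv_value):
        """Bias potential (k_BT) at CV values, linearly interpolated."""
        vals = np.atleast_1d(np.asarray(cv_value, dtype=np.float64))
        out = np.array([_bias_value(self.grid, self.grid_min, self.grid_spacing, v) for v in vals])
        return float(out[0]) if np.ndim(cv_value) == 0 else out

    def bias_force(self, x: float, y: float, x0: float = 0.0, y0: float = 0.0):
        """(-dV/dx, -dV/dy) in k_BT/Angstrom through the CV chain rule."""
        u = float(self.cv.shifted_value(x, y, x0, y0))
        dv = _bias_deriv(self.grid, self.grid_min, self.grid_spacing, u)
        c, s = math.cos(self.cv.theta_rad), math.sin(self.cv.theta_rad)
        return -dv * c, -dv * s

    def zero_bias(self) -> None:
        """Clear the bias table and restart the deposition count."""
        self.grid[:] = 0.0
        self.n_hills = 0

    def bias_table(self, path=None) -> np.ndarray:
        """(cv, bias) table; optionally dumped as two-column text."""
        cvs = self.grid_min + self.grid_spacing * np.arange(self.grid.size)
        table = np.column_stack([cvs, self.grid])
        if path is not None:
            np.savetxt(path, table, header="cv bias_kt", fmt="%.8g")
        return table
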