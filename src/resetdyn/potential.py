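"""Analytic 2D model potentials: energy, gradient, and landscape diagnostics.

All surfaces report energies as dimensionless multiples of k_B*T at the
reference temperature and lengths in Angstrom.  The main surface is a
modified Faradjian-Elber potential: a symmetric double well along x whose
wells are separated by a Gaussian ridge that is pierced, near y = 0, by a
much lower saddle channel,

    U(x, y) = A1 (x^8 + y'^8) + A2 exp(-x^2 / (2 s1^2)) (1 - B exp(-y^2 / (2 s2^2)))

with y' = yscale * y.  The y-rescaling stretches the soft y'^8 confinement
by 1/yscale (to roughly +/-40 Angstrom at the defaults) while the saddle
channel keeps its bare width of about sigma2, which is what makes
first-passage times broadly distributed: a walker that wanders away along
y faces the full A2 ridge and must diffuse back to the narrow channel
before it can cross.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = [
    "PotentialSurface",
    "LandscapeReport",
    "modified_faradjian_elber",
    "double_well_1d",
    "harmonic",
    "free_particle",
    "linear_tilt",
    "surface_from_config",
    "analyze_landscape",
]

# Integer codes dispatching the analytic form inside numba kernels.
KIND_FARADJIAN_ELBER = 0
KIND_DOUBLE_WELL = 1
KIND_FREE = 2
KIND_HARMONIC = 3
KIND_LINEAR = 4


@njit(cache=True)
def _energy_scalar(kind, p, x, y):
    if kind == KIND_FARADJIAN_ELBER:
        a1, a2, b, s1, s2, ys = p[0], p[1], p[2], p[3], p[4], p[5]
        yp = ys * y
        g1 = np.exp(-x * x / (2.0 * s1 * s1))
        g2 = np.exp(-y * y / (2.0 * s2 * s2))
        return a1 * (x**8 + yp**8) + a2 * g1 * (1.0 - b * g2)
    elif kind == KIND_DOUBLE_WELL:
        h, a, ky = p[0], p[1], p[2]
        q = (x / a) ** 2 - 1.0
        return h * q * q + 0.5 * ky * y * y
    elif kind == KIND_HARMONIC:
        return 0.5 * p[0] * x * x + 0.5 * p[1] * y * y
    elif kind == KIND_LINEAR:
        return p[0] * x
    return 0.0


@njit(cache=True)
def _grad_scalar(kind, p, x, y):
    """(dU/dx, dU/dy) in k_BT / Angstrom."""
    if kind == KIND_FARADJIAN_ELBER:
        a1, a2, b, s1, s2, ys = p[0], p[1], p[2], p[3], p[4], p[5]
        yp = ys * y
        g1 = np.exp(-x * x / (2.0 * s1 * s1))
        g2 = np.exp(-y * y / (2.0 * s2 * s2))
        dx = 8.0 * a1 * x**7 - (x / (s1 * s1)) * a2 * g1 * (1.0 - b * g2)
        dy = 8.0 * a1 * yp**7 * ys + a2 * g1 * b * g2 * (y / (s2 * s2))
        return dx, dy
    elif kind == KIND_DOUBLE_WELL:
        h, a, ky = p[0], p[1], p[2]
        q = (x / a) ** 2 - 1.0
        return 4.0 * h * q * x / (a * a), ky * y
    elif kind == KIND_HARMONIC:
        return p[0] * x, p[1] * y
    elif kind == KIND_LINEAR:
        return p[0], 0.0
    return 0.0, 0.0


@njit(cache=True)
def _energy_array(kind, p, xs, ys, out):
    for i in range(xs.size):
        out[i] = _energy_scalar(kind, p, xs[i], ys[i])


@njit(cache=True)
def _grad_array(kind, p, xs, ys, outx, outy):
    for i in range(xs.size):
        gx, gy = _grad_scalar(kind, p, xs[i], ys[i])
        outx[i] = gx
        outy[i] = gy


@dataclasses.dataclass(frozen=True)
class PotentialSurface:
    """An analytic 2D energy surface with exact gradients.

    Parameters are stored both as a name->value map (``parameters``) and as
    the packed float array consumed by the compiled kernels.
    """

    name: str
    kind: int
    parameters: dict
    _packed: np.ndarray

    def energy(self, x, y):
        """Potential energy in k_BT; broadcasts over array input."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        bx, by = np.broadcast_arrays(x, y)
        out = np.empty(bx.size, dtype=np.float64)
        _energy_array(self.kind, self._packed, bx.ravel(), by.ravel(), out)
        out = out.reshape(bx.shape)
        return float(out) if out.ndim == 0 else out

    def gradient(self, x, y):
        """(dU/dx, dU/dy) in k_BT/Angstrom; broadcasts over array input."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        bx, by = np.broadcast_arrays(x, y)
        gx = np.empty(bx.size, dtype=np.float64)
        gy = np.empty(bx.size, dtype=np.float64)
        _grad_array(self.kind, self._packed, bx.ravel(), by.ravel(), gx, gy)
        gx = gx.reshape(bx.shape)
        gy = gy.reshape(bx.shape)
        if gx.ndim == 0:
            return float(gx), float(gy)
        return gx, gy

    def force(self, x, y):
        """(-dU/dx, -dU/dy) in k_BT/Angstrom."""
        gx, gy = self.gradient(x, y)
        if np.ndim(gx) == 0:
            return -gx, -gy
        return -gx, -gy


def modified_faradjian_elber(
    a1: float = 1.2e-5,
    a2: float = 12.0,
    b: float = 0.75,
    sigma1: float = 1.0,
    sigma2: float = 0.5,
    yscale: float = 0.1,
) -> PotentialSurface:
    """Modified Faradjian-Elber surface.

    Defaults give a ridge of ``a2`` = 12 k_BT along x = 0, a saddle channel
    of ``a2 * (1 - b)`` = 3 k_BT around y = 0 of width ``sigma2``, minima
    near x = +/-3 Angstrom, and a soft y'^8 confinement reaching 1 k_BT at
    |y| of about 4.1 / ``yscale``.
    """
    params = dict(A1=a1, A2=a2, B=b, sigma1=sigma1, sigma2=sigma2, yscale=yscale)
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("Gaussian widths must be positive")
    packed = np.array([a1, a2, b, sigma1, sigma2, yscale], dtype=np.float64)
    return PotentialSurface("modified_faradjian_elber", KIND_FARADJIAN_ELBER, params, packed)


def double_well_1d(
    barrier_kt: float = 4.0, half_separation: float = 3.0, transverse_k: float = 1.0
) -> PotentialSurface:
    """Symmetric quartic double well along x with harmonic confinement in y.

    ``U = barrier_kt * ((x/a)^2 - 1)^2 + transverse_k * y^2 / 2`` has minima
    at x = +/-``half_separation`` and a barrier of exactly ``barrier_kt`` at
    x = 0.
    """
    if barrier_kt <= 0:
        raise ValueError("barrier height must be positive")
    if half_separation <= 0:
        raise ValueError("minima separation must be positive")
    params = dict(barrier_kt=barrier_kt, half_separation=half_separation, transverse_k=transverse_k)
    packed = np.array([barrier_kt, half_separation, transverse_k], dtype=np.float64)
    return PotentialSurface("double_well_1d", KIND_DOUBLE_WELL, params, packed)


def harmonic(kx: float = 1.0, ky: float = 1.0) -> PotentialSurface:
    """Harmonic well U = kx x^2/2 + ky y^2/2 (k in k_BT / Ang^2)."""
    packed = np.array([kx, ky], dtype=np.float64)
    return PotentialSurface("harmonic", KIND_HARMONIC, dict(kx=kx, ky=ky), packed)


def free_particle() -> PotentialSurface:
    """Zero potential (free diffusion)."""
    return PotentialSurface("free", KIND_FREE, {}, np.zeros(1))


def linear_tilt(slope: float) -> PotentialSurface:
    """Constant-force potential U = slope * x (slope in k_BT / Ang)."""
    return PotentialSurface("linear", KIND_LINEAR, dict(slope=slope), np.array([slope]))


_FACTORIES: dict[str, Callable] = {
    "modified_faradjian_elber": modified_faradjian_elber,
    "double_well_1d": double_well_1d,
    "harmonic": harmonic,
    "free": free_particle,
    "linear": linear_tilt,
}


def surface_from_config(config: dict) -> PotentialSurface:
    """Build a surface from a plain config mapping with a ``surface`` key.

    Remaining keys are passed to the factory, mirroring the analytic symbols
    (e.g. ``{"surface": "modified_faradjian_elber", "A2": 4.0, "B": 0.625}``).
    """
    cfg = dict(config)
    name = cfg.pop("surface", None)
    if name not in _FACTORIES:
        raise ValueError(f"unknown surface name: {name!r}")
    # accept the printed parameter symbols case-insensitively
    remap = {"a1": "a1", "a2": "a2", "b": "b", "sigma1": "sigma1", "sigma2": "sigma2", "yscale": "yscale"}
    kwargs = {}
    for key, value in cfg.items():
        kwargs[remap.get(key.lower(), key)] = float(value)
    return _FACTORIES[name](**kwargs)


@dataclasses.dataclass
class LandscapeReport:
    """Stationary-point and barrier diagnostics for a surface."""

    surface: PotentialSurface
    minima: list[tuple[float, float]]
    global_minimum_energy: float
    barrier_profile: Callable[[float], float]

    def saddle_barrier(self) -> float:
        """Barrier along x at y = 0, relative to the global minimum (k_BT)."""
        return self.barrier_profile(0.0)

    def ridge_barrier(self, y_far: float = 200.0) -> float:
        """Barrier along x far from the saddle channel (k_BT)."""
        return self.barrier_profile(y_far)


def analyze_landscape(
    surface: PotentialSurface,
    x_range: tuple[float, float] = (-6.0, 6.0),
    y_range: tuple[float, float] = (-6.0, 6.0),
    spacing: float = 0.05,
    ridge_window: tuple[float, float] = (-1.0, 1.0),
    grad_tol: float = 1e-8,
) -> LandscapeReport:
    """Locate minima by grid scan plus gradient refinement and measure barriers.

    ``barrier_profile(y)`` is the maximum of U over x in ``ridge_window`` at
    that y (the barrier is centred at x = 0 for every supported surface),
    minus the global-minimum energy.
    """
    xs = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
    ys = np.arange(y_range[0], y_range[1] + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    u = surface.energy(gx, gy)

    # local minima on the interior of the grid
    candidates = []
    interior = u[1:-1, 1:-1]
    lower = (
        (interior <= u[:-2, 1:-1])
        & (interior <= u[2:, 1:-1])
        & (interior <= u[1:-1, :-2])
        & (interior <= u[1:-1, 2:])
    )
    for i, j in zip(*np.nonzero(lower)):
        candidates.append((xs[i + 1], ys[j + 1]))

    def fun(z):
        return surface.energy(z[0], z[1])

    def jac(z):
        return np.array(surface.gradient(z[0], z[1]))

    minima: list[tuple[float, float]] = []
    for x0, y0 in candidates:
        res = minimize(fun, [x0, y0], jac=jac, method="BFGS", options={"gtol": 1e-12})
        if not np.all(np.isfinite(res.x)):
            continue
        if np.linalg.norm(jac(res.x)) > grad_tol:
            continue
        if not (x_range[0] <= res.x[0] <= x_range[1] and y_range[0] <= res.x[1] <= y_range[1]):
            continue
        if any(np.hypot(res.x[0] - mx, res.x[1] - my) < 10 * spacing for mx, my in minima):
            continue
        minima.append((float(res.x[0]), float(res.x[1])))
    if not minima:
        raise RuntimeError("no minimum found in the scanned range")
    minima.sort(key=lambda m: surface.energy(m[0], m[1]))
    u_min = float(surface.energy(*minima[0]))

    ridge_x = np.linspace(ridge_window[0], ridge_window[1], 4001)

    def barrier_profile(y: float) -> float:
        return float(np.max(surface.energy(ridge_x, np.full_like(ridge_x, y))) - u_min)

    return LandscapeReport(surface, minima, u_min, barrier_profile)
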