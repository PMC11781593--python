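"""Batched underdamped Langevin integration with first-passage detection.

The integrator is a BAOAB splitting of underdamped Langevin dynamics: half
kick, half drift, Ornstein-Uhlenbeck velocity refresh, half drift, half
kick.  At zero friction it reduces exactly to velocity Verlet.  Walkers are
propagated one at a time by a compiled kernel; each walker owns an RNG
stream seeded from the master seed through ``numpy.random.SeedSequence``,
so ensembles are bit-reproducible and independent of how they are batched.

The kernel optionally layers stochastic resetting (standard or informed,
see :mod:`resetdyn.resetting`) and well-tempered Metadynamics
(:mod:`resetdyn.metad`) on the plain dynamics, records a strided CV series,
and stops each walker when its raw x-coordinate crosses the first-passage
threshold.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .metad import _bias_deriv, _deposit
from .potential import PotentialSurface, _grad_scalar
from .units import FS_PER_NS, kt, thermal_velocity

__all__ = [
    "SimConfig",
    "SimState",
    "StopCondition",
    "TrajectoryRecord",
    "FPTEnsemble",
    "sample_maxwell_boltzmann",
    "step",
    "run_trajectory",
    "run_until_fpt",
]

# resetting-condition modes used by the kernel
COND_NONE = 0
COND_ALWAYS = 1
COND_GREATER = 2
COND_LESS = 3


@dataclasses.dataclass
class SimConfig:
    """Langevin simulation settings (K, fs^-1, fs, g/mol)."""

    temperature: float = 300.0
    friction: float = 0.01
    dt: float = 1.0
    mass: float = 40.0
    max_steps: int = 400_000_000
    fpt_check_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.mass <= 0 or self.temperature <= 0:
            raise ValueError("dt, mass and temperature must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")

    @property
    def kt(self) -> float:
        return kt(self.temperature)


@dataclasses.dataclass
class SimState:
    """Instantaneous single-walker state (Ang, Ang/fs, fs)."""

    x: float
    y: float
    vx: float
    vy: float
    time: float = 0.0


@dataclasses.dataclass(frozen=True)
class StopCondition:
    """First passage on the raw x-coordinate: default x < -1 Angstrom."""

    threshold: float = -1.0
    direction: str = "below"

    def __post_init__(self):
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")

    def satisfied(self, x: float) -> bool:
        return x < self.threshold if self.direction == "below" else x > self.threshold


@dataclasses.dataclass
class TrajectoryRecord:
    """Outcome of one walker: first-passage time, resets, strided CV series."""

    fpt_ns: float
    n_steps: int
    reset_count: int
    censored: bool
    cv_series: np.ndarray        # float32, CV at steps stride, 2*stride, ...
    cv_stride: int
    reset_steps: np.ndarray      # int64 step indices of executed resets
    dt_fs: float
    final_state: SimState


class FPTEnsemble:
    """A set of first-passage times with summary statistics.

    Censored walkers (those that hit ``max_steps``) are kept in ``records``
    and counted, but excluded from the mean; a warning is emitted when any
    are present.
    """

    def __init__(self, records: Sequence[TrajectoryRecord]):
        if len(records) == 0:
            raise ValueError("empty ensemble")
        self.records = list(records)
        self.fpts_ns = np.array([r.fpt_ns for r in self.records if not r.censored])
        self.n_censored = sum(r.censored for r in self.records)
        if self.n_censored:
            warnings.warn(
                f"{self.n_censored}/{len(self.records)} walkers censored at max_steps; "
                "they are excluded from the MFPT",
                stacklevel=2,
            )
        if self.fpts_ns.size == 0:
            raise ValueError("all walkers censored; raise max_steps")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mfpt_ns(self) -> float:
        return float(np.mean(self.fpts_ns))

    @property
    def sem_ns(self) -> float:
        n = self.fpts_ns.size
        return float(np.std(self.fpts_ns, ddof=1) / math.sqrt(n)) if n > 1 else math.inf

    @property
    def cv(self) -> float:
        """Coefficient of variation of the FPT distribution."""
        return float(np.std(self.fpts_ns, ddof=1) / np.mean(self.fpts_ns))

    @property
    def mean_resets(self) -> float:
        return float(np.mean([r.reset_count for r in self.records if not r.censored]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "walker": np.arange(len(self.records)),
                "fpt_ns": [r.fpt_ns for r in self.records],
                "n_resets": [r.reset_count for r in self.records],
                "censored": [r.censored for r in self.records],
            }
        )


def sample_maxwell_boltzmann(temperature: float, mass: float, rng: np.random.Generator, size=None):
    """Thermal velocity components: Gaussian, zero mean, variance k_BT/m."""
    return rng.normal(0.0, thermal_velocity(temperature, mass), size=size)


# ---------------------------------------------------------------------------
# single-step integration (reference path, shared semantics with the kernel)
# ---------------------------------------------------------------------------

def step(
    state: SimState,
    surface: PotentialSurface,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    external_bias_force=None,
) -> SimState:
    """Advance one BAOAB step and return the new state.

    ``external_bias_force(x, y) -> (fx, fy)`` supplies an additional force
    in k_BT/Angstrom (e.g. a MetaD bias).  With ``friction == 0`` and no
    noise source the update is symplectic velocity Verlet.
    """
    kt_ = config.kt
    dt = config.dt
    c1 = math.exp(-config.friction * dt)
    c3 = math.sqrt(kt_ / config.mass * (1.0 - c1 * c1))

    def total_force(x, y):
        gx, gy = surface.gradient(x, y)
        fx, fy = -gx, -gy
        if external_bias_force is not None:
            bx, by = external_bias_force(x, y)
            fx += bx
            fy += by
        if not (math.isfinite(fx) and math.isfinite(fy)):
            raise FloatingPointError(f"non-finite force at position ({x}, {y})")
        return fx * kt_, fy * kt_

    fx, fy = total_force(state.x, state.y)
    vx = state.vx + 0.5 * dt * fx / config.mass
    vy = state.vy + 0.5 * dt * fy / config.mass
    x = state.x + 0.5 * dt * vx
    y = state.y + 0.5 * dt * vy
    if config.friction > 0.0:
        if rng is None:
            raise ValueError("rng required when friction > 0")
        vx = c1 * vx + c3 * rng.standard_normal()
        vy = c1 * vy + c3 * rng.standard_normal()
    x += 0.5 * dt * vx
    y += 0.5 * dt * vy
    fx, fy = total_force(x, y)
    vx += 0.5 * dt * fx / config.mass
    vy += 0.5 * dt * fy / config.mass
    return SimState(x, y, vx, vy, state.time + dt)


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _equilibrium_kernel(kind, pparams, seed, x0, y0, kt_, gamma, dt, mass, n_steps, stride):
    np.random.seed(seed)
    c1 = np.exp(-gamma * dt)
    c3 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))
    vth = np.sqrt(kt_ / mass)
    x, y = x0, y0
    vx = vth * np.random.normal()
    vy = vth * np.random.normal()
    gx, gy = _grad_scalar(kind, pparams, x, y)
    fx, fy = -gx * kt_, -gy * kt_
    nrec = n_steps // stride
    out = np.empty((nrec, 4), dtype=np.float64)
    k = 0
    for s in range(1, n_steps + 1):
        vx += 0.5 * dt * fx / mass
        vy += 0.5 * dt * fy / mass
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        if gamma > 0.0:
            vx = c1 * vx + c3 * np.random.normal()
            vy = c1 * vy + c3 * np.random.normal()
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        gx, gy = _grad_scalar(kind, pparams, x, y)
        fx, fy = -gx * kt_, -gy * kt_
        vx += 0.5 * dt * fx / mass
        vy += 0.5 * dt * fy / mass
        if s % stride == 0 and k < nrec:
            out[k, 0] = x
            out[k, 1] = y
            out[k, 2] = vx
            out[k, 3] = vy
            k += 1
    return out[:k]


@njit(cache=True, fastmath=True)
def _fpt_kernel(
    kind, pparams, seed,
    x0, y0, rx, ry,
    kt_, gamma, dt, mass,
    max_steps, fpt_stride,
    stop_thr, stop_below,
    r_per_fs, cond_mode, cond_c, portal,
    cos_t, sin_t,
    metad_on, pace, height, sigma, biasfactor, grid, gmin, gdx,
    rec_stride,
):
    """Propagate one walker to first passage.

    Returns (n_steps, n_resets, cv_series, reset_steps, x, y, vx, vy);
    n_steps is -1 if the walker was censored at max_steps.  Per step the
    order of business is: integrate, record the CV, test first passage,
    deposit a hill if due, then run the resetting trial — so a walker that
    passes at step n is never reset at step n, the convention the
    first-passage predictor shares.
    """
    np.random.seed(seed)
    c1 = np.exp(-gamma * dt)
    c3 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))
    vth = np.sqrt(kt_ / mass)

    x, y = x0, y0
    vx = vth * np.random.normal()
    vy = vth * np.random.normal()

    gx, gy = _grad_scalar(kind, pparams, x, y)
    fx, fy = -gx * kt_, -gy * kt_
    if metad_on:
        du = _bias_deriv(grid, gmin, gdx, x0 + cos_t * (x - x0) + sin_t * (y - y0))
        fx -= du * cos_t * kt_
        fy -= du * sin_t * kt_

    have_reset = cond_mode != COND_NONE and (r_per_fs > 0.0 or portal)
    if have_reset and not portal:
        next_reset = np.random.exponential() / r_per_fs
    else:
        next_reset = 1.0e300

    cvbuf = np.empty(8192, dtype=np.float32)
    ncv = 0
    rsbuf = np.empty(256, dtype=np.int64)
    nres = 0
    hill_clock = 0

    # a walker born past the target passes immediately
    if (x < stop_thr) if stop_below else (x > stop_thr):
        return 0, 0, cvbuf[:0], rsbuf[:0], x, y, vx, vy

    n_steps = -1
    u = x0  # rotated CV; refreshed wherever it is consumed
    for s in range(1, max_steps + 1):
        vx += 0.5 * dt * fx / mass
        vy += 0.5 * dt * fy / mass
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        if gamma > 0.0:
            vx = c1 * vx + c3 * np.random.normal()
            vy = c1 * vy + c3 * np.random.normal()
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        gx, gy = _grad_scalar(kind, pparams, x, y)
        fx, fy = -gx * kt_, -gy * kt_
        if metad_on:
            u = x0 + cos_t * (x - x0) + sin_t * (y - y0)
            du = _bias_deriv(grid, gmin, gdx, u)
            fx -= du * cos_t * kt_
            fy -= du * sin_t * kt_
        vx += 0.5 * dt * fx / mass
        vy += 0.5 * dt * fy / mass

        if s % 4096 == 0 and not (np.isfinite(fx) and np.isfinite(fy)):
            raise FloatingPointError("non-finite force encountered")

        if rec_stride > 0 and s % rec_stride == 0:
            if not metad_on:
                u = x0 + cos_t * (x - x0) + sin_t * (y - y0)
            if ncv == cvbuf.size:
                nb = np.empty(cvbuf.size * 2, dtype=np.float32)
                nb[:ncv] = cvbuf
                cvbuf = nb
            cvbuf[ncv] = u
            ncv += 1

        if s % fpt_stride == 0:
            if (x < stop_thr) if stop_below else (x > stop_thr):
                n_steps = s
                break

        if metad_on:
            hill_clock += 1
            if hill_clock == pace:
                hill_clock = 0
                _deposit(grid, gmin, gdx, sigma, height, biasfactor, u)
                # bias changed: refresh the cached force for the next step
                du = _bias_deriv(grid, gmin, gdx, u)
                gx, gy = _grad_scalar(kind, pparams, x, y)
                fx = (-gx - du * cos_t) * kt_
                fy = (-gy - du * sin_t) * kt_

        if have_reset:
            t = s * dt
            due = False
            if portal:
                due = True
            elif t >= next_reset:
                due = True
                while next_reset <= t:
                    next_reset += np.random.exponential() / r_per_fs
            if due:
                if not metad_on:
                    u = x0 + cos_t * (x - x0) + sin_t * (y - y0)
                ok = True
                if cond_mode == COND_GREATER:
                    ok = u > cond_c
                elif cond_mode == COND_LESS:
                    ok = u < cond_c
                if ok:
                    x, y = rx, ry
                    vx = vth * np.random.normal()
                    vy = vth * np.random.normal()
                    if metad_on:
                        grid[:] = 0.0
                        hill_clock = 0
                    gx, gy = _grad_scalar(kind, pparams, x, y)
                    fx, fy = -gx * kt_, -gy * kt_
                    if nres == rsbuf.size:
                        nb2 = np.empty(rsbuf.size * 2, dtype=np.int64)
                        nb2[:nres] = rsbuf
                        rsbuf = nb2
                    rsbuf[nres] = s
                    nres += 1
    return n_steps, nres, cvbuf[:ncv].copy(), rsbuf[:nres].copy(), x, y, vx, vy


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def run_trajectory(
    surface: PotentialSurface,
    config: SimConfig,
    n_steps: int,
    start: tuple[float, float] = (0.0, 0.0),
    sample_stride: int = 100,
    seed: Optional[int] = None,
):
    """Plain equilibrium run; returns an (n, 4) array of (x, y, vx, vy) samples."""
    s = config.seed if seed is None else seed
    walker_seed = int(np.random.SeedSequence(s).generate_state(1)[0])
    return _equilibrium_kernel(
        surface.kind, surface._packed, walker_seed,
        float(start[0]), float(start[1]),
        config.kt, config.friction, config.dt, config.mass,
        int(n_steps), int(sample_stride),
    )


def run_until_fpt(
    surface: PotentialSurface,
    config: SimConfig,
    stop: StopCondition,
    n_walkers: int,
    start: tuple[float, float] = (3.0, 0.0),
    protocol=None,
    metad=None,
    record_stride: int = 0,
) -> FPTEnsemble:
    """Run ``n_walkers`` independent walkers from ``start`` to first passage.

    ``protocol`` is a :class:`resetdyn.resetting.ResetProtocol` (or None for
    plain dynamics) and ``metad`` a :class:`resetdyn.metad.MetaDEngine`
    template — each walker receives its own zeroed copy of the bias table.
    ``record_stride`` > 0 stores the resetting CV every that many steps.
    Initial velocities are Maxwell-Boltzmann; each walker's RNG stream is
    derived from ``config.seed`` so results do not depend on batch size.
    """
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_walkers)

    r_per_fs = 0.0
    cond_mode = COND_NONE
    cond_c = 0.0
    portal = False
    theta = 0.0
    rx, ry = float(start[0]), float(start[1])
    if protocol is not None:
        r_per_fs = protocol.rate_ns_inv / FS_PER_NS
        portal = bool(getattr(protocol, "portal", False))
        if r_per_fs > 0.0 or portal:
            if protocol.threshold is None:
                cond_mode = COND_ALWAYS
            else:
                cond_mode = COND_GREATER if protocol.direction == "greater" else COND_LESS
                cond_c = float(protocol.threshold)
        theta = math.radians(getattr(protocol, "theta_deg", 0.0))
        if protocol.reset_target is not None:
            rx, ry = map(float, protocol.reset_target)

    metad_on = metad is not None
    if metad_on:
        theta_m = metad.cv.theta_rad
        if protocol is not None and getattr(protocol, "theta_deg", 0.0) != metad.cv.theta_deg:
            raise ValueError("resetting protocol and MetaD must share the CV rotation")
        theta = theta_m
        pace, height, sigma, biasfactor = metad.pace, metad.height_kt, metad.sigma, metad.biasfactor
        gmin, gdx, ngrid = metad.grid_min, metad.grid_spacing, metad.grid.size
    else:
        pace, height, sigma, biasfactor = 1, 0.0, 1.0, 10.0
        gmin, gdx, ngrid = -1.0, 1.0, 2

    cos_t, sin_t = math.cos(theta), math.sin(theta)
    stop_below = stop.direction == "below"

    records = []
    for i in range(n_walkers):
        grid = np.zeros(ngrid, dtype=np.float64)
        n_steps, nres, cvs, rsteps, xf, yf, vxf, vyf = _fpt_kernel(
            surface.kind, surface._packed, int(seeds[i]),
            float(start[0]), float(start[1]), rx, ry,
            config.kt, config.friction, config.dt, config.mass,
            int(config.max_steps), int(config.fpt_check_stride),
            float(stop.threshold), stop_below,
            r_per_fs, cond_mode, cond_c, portal,
            cos_t, sin_t,
            metad_on, pace, height, sigma, biasfactor, grid, gmin, gdx,
            int(record_stride),
        )
        censored = n_steps < 0
        fpt_fs = (config.max_steps if censored else n_steps) * config.dt
        records.append(
            TrajectoryRecord(
                fpt_ns=float("nan") if censored else fpt_fs / FS_PER_NS,
                n_steps=config.max_steps if censored else int(n_steps),
                reset_count=int(nres),
                censored=censored,
                cv_series=cvs,
                cv_stride=int(record_stride),
                reset_steps=rsteps,
                dt_fs=config.dt,
                final_state=SimState(xf, yf, vxf, vyf, fpt_fs),
            )
        )
    return FPTEnsemble(records)
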