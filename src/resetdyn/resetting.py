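"""Stochastic resetting protocols: standard and informed.

Standard stochastic resetting (SR) restarts a trajectory at exponentially
distributed epochs regardless of where it is.  Informed stochastic
resetting (ISR) executes the restart only when a condition on a collective
variable holds at the epoch — here, the rotated-x CV being beyond a
threshold c; otherwise the trajectory continues to the next epoch and the
condition is rechecked.  On reset the position returns to the exact initial
point and only the momenta are resampled thermally; the elapsed clock keeps
running, so first-passage times include all time spent before resets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .dynamics import FPTEnsemble, SimState, sample_maxwell_boltzmann

__all__ = ["ResetProtocol", "ResetEvent", "draw_reset_time", "attempt_reset", "speedup"]


@dataclasses.dataclass(frozen=True)
class ResetProtocol:
    """Resetting at rate ``rate_ns_inv`` gated by a CV condition.

    ``threshold=None`` is the always-true condition (standard SR).  With a
    threshold c, direction ``"greater"`` resets when cv > c (the informed
    protocol for a target lying at smaller cv).  ``theta_deg`` rotates the
    CV (and with it the threshold line, about the start point); 0 means the
    raw x-coordinate.  ``portal=True`` replaces the exponential clock with a
    deterministic every-step check — the r -> infinity teleporting limit.
    """

    rate_ns_inv: float
    threshold: Optional[float] = None
    direction: str = "greater"
    theta_deg: float = 0.0
    reset_target: Optional[tuple[float, float]] = None
    portal: bool = False

    def __post_init__(self):
        if self.rate_ns_inv < 0:
            raise ValueError("resetting rate must be non-negative")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")

    def condition(self, x: float, y: float, origin: tuple[float, float] = (3.0, 0.0)) -> bool:
        """Is the reset condition satisfied at (x, y)?"""
        if self.threshold is None:
            return True
        th = math.radians(self.theta_deg)
        u = origin[0] + math.cos(th) * (x - origin[0]) + math.sin(th) * (y - origin[1])
        return u > self.threshold if self.direction == "greater" else u < self.threshold


@dataclasses.dataclass(frozen=True)
class ResetEvent:
    """One resetting epoch: when it occurred and whether it fired."""

    time_fs: float
    condition_satisfied: bool


def draw_reset_time(rate_ns_inv: float, rng: np.random.Generator) -> float:
    """Exponential waiting time to the next resetting epoch, in ns.

    Rate zero returns ``inf`` (no resetting ever).
    """
    if rate_ns_inv < 0:
        raise ValueError("rate must be non-negative")
    if rate_ns_inv == 0:
        return math.inf
    return float(rng.exponential(1.0 / rate_ns_inv))


def attempt_reset(
    state: SimState,
    protocol: ResetProtocol,
    rng: np.random.Generator,
    origin: tuple[float, float] = (3.0, 0.0),
    temperature: float = 300.0,
    mass: float = 40.0,
    metad=None,
) -> tuple[SimState, ResetEvent]:
    """Execute one resetting epoch reached at ``state.time``.

    If the protocol condition holds, the position jumps to the reset target
    (the origin by default), momenta are redrawn thermally and any MetaD
    engine's bias is zeroed; otherwise the state is returned unchanged.
    """
    ok = protocol.condition(state.x, state.y, origin)
    event = ResetEvent(time_fs=state.time, condition_satisfied=ok)
    if not ok:
        return state, event
    target = protocol.reset_target if protocol.reset_target is not None else origin
    vx, vy = sample_maxwell_boltzmann(temperature, mass, rng, size=2)
    if metad is not None:
        metad.zero_bias()
    return SimState(target[0], target[1], float(vx), float(vy), state.time), event


def speedup(baseline: FPTEnsemble, accelerated: FPTEnsemble) -> tuple[float, float]:
    """MFPT ratio baseline/accelerated and its delta-method standard error."""
    mb, ma = baseline.mfpt_ns, accelerated.mfpt_ns
    if ma <= 0:
        raise ValueError("accelerated MFPT must be positive")
    ratio = mb / ma
    rel = math.sqrt((baseline.sem_ns / mb) ** 2 + (accelerated.sem_ns / ma) ** 2)
    return ratio, ratio * rel
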