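"""Kinetics inference from accelerated ensembles.

Two inverse problems are solved here.  First, recovering the unbiased
(r = 0) MFPT from an ensemble run WITH informed resetting at one rate r*:
because independent exponential clocks superpose (two clocks at r* and
r - r* are one clock at r), predicting the MFPT at any probe rate r > r*
only requires reweighting the recorded r* trajectories for the extra clock
at r - r* — the same survival machinery as the reset-free predictor, with
the recorded trajectories (resets and all) playing the role of the sample.
Fitting the probe-rate curve locally and extrapolating to r = 0 then
estimates the unbiased MFPT, trading accuracy for the speedup earned at r*.

Second, direct transit times (DTTs): the committed part of a barrier
crossing, measured from the last time step on the far side of an upper
surface to the first time step past a lower surface along a CV.  DTTs are
far shorter than FPTs and depend only weakly on the bias that accelerated
the trajectory, which makes them inferable at speedups where the MFPT no
longer is.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from .dynamics import FPTEnsemble
from .predictor import ResetFreeSample, predict_mfpt
from .resetting import ResetProtocol

__all__ = [
    "InferenceResult",
    "TransitConfig",
    "tau_at_higher_rates",
    "extrapolate_to_zero",
    "infer_unbiased_mfpt",
    "extract_dtt",
    "mean_dtt",
]


def tau_at_higher_rates(
    ensemble: FPTEnsemble,
    protocol: ResetProtocol,
    probe_rates_ns_inv: Sequence[float],
    n_boot: int = 100,
    seed: int = 0,
):
    """<tau>_r at probe rates r >= r* from an ensemble already run at r*.

    The ensemble must have been recorded with a CV stride
    (``record_stride`` in :func:`resetdyn.dynamics.run_until_fpt`).  Each
    probe applies the reset-free predictor with the rate increment
    r - r* and the protocol's own threshold; the probe at r* itself returns
    the ensemble's empirical MFPT.  Returns (tau_ns, se_ns) arrays.
    """
    r_star = protocol.rate_ns_inv
    probe = np.asarray(probe_rates_ns_inv, dtype=np.float64)
    if np.any(probe < r_star):
        raise ValueError("probe rates must be >= the simulated rate r*")
    sample = ResetFreeSample.from_ensemble(ensemble)
    taus = np.empty(probe.size)
    ses = np.empty(probe.size)
    for i, r in enumerate(probe):
        res = predict_mfpt(
            sample, r - r_star, protocol.threshold, protocol.direction,
            n_boot=n_boot, seed=seed + i,
        )
        taus[i] = res.mfpt_ns
        ses[i] = res.se_ns
    return taus, ses


@dataclasses.dataclass
class InferenceResult:
    """Extrapolated unbiased MFPT with the probe curve that produced it."""

    r_star_ns_inv: float
    probe_rates_ns_inv: np.ndarray
    tau_ns: np.ndarray
    tau_se_ns: np.ndarray
    coefficients: np.ndarray   # polynomial in r for log tau, highest power first
    mfpt_ns: float             # extrapolated to r = 0
    se_ns: float

    def fold_error(self, reference_mfpt_ns: float) -> float:
        """max(estimate/reference, reference/estimate) - 1 as a fold factor."""
        a, b = self.mfpt_ns, reference_mfpt_ns
        return max(a / b, b / a)


def extrapolate_to_zero(
    probe_rates_ns_inv,
    tau_ns,
    r_star_ns_inv: float,
    tau_se_ns=None,
    degree: int = 2,
) -> InferenceResult:
    """Fit log <tau>_r as a low-order polynomial in r and evaluate at r = 0.

    Points are weighted by their estimated relative errors when provided.
    At least ``degree + 1`` probe points are required; the fit covariance
    supplies the uncertainty of the extrapolated value when there are
    enough points for it.
    """
    r = np.asarray(probe_rates_ns_inv, dtype=np.float64)
    tau = np.asarray(tau_ns, dtype=np.float64)
    if r.size != tau.size or r.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} probe points")
    if np.any(tau <= 0):
        raise ValueError("probe MFPTs must be positive")
    logtau = np.log(tau)
    if tau_se_ns is not None:
        se = np.asarray(tau_se_ns, dtype=np.float64)
        sigma = np.where(np.isfinite(se) & (se > 0), se / tau, np.nan)
        fallback = np.nanmedian(sigma) if np.any(np.isfinite(sigma)) else 1.0
        sigma = np.where(np.isfinite(sigma), sigma, fallback)
        w = 1.0 / sigma
    else:
        w = None

    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            if r.size >= degree + 3:
                coeffs, cov = np.polyfit(r, logtau, degree, w=w, cov="unscaled" if w is not None else True)
                var0 = cov[-1, -1]
            else:
                coeffs = np.polyfit(r, logtau, degree, w=w)
                var0 = np.nan
        except np.exceptions.RankWarning as exc:
            raise ValueError("ill-conditioned extrapolation fit; spread the probe rates") from exc

    mfpt0 = float(np.exp(coeffs[-1]))
    se0 = float(mfpt0 * np.sqrt(var0)) if np.isfinite(var0) else float("nan")
    return InferenceResult(
        r_star_ns_inv=float(r_star_ns_inv),
        probe_rates_ns_inv=r,
        tau_ns=tau,
        tau_se_ns=np.asarray(tau_se_ns) if tau_se_ns is not None else np.full_like(tau, np.nan),
        coefficients=coeffs,
        mfpt_ns=mfpt0,
        se_ns=se0,
    )


def infer_unbiased_mfpt(
    ensemble: FPTEnsemble,
    protocol: ResetProtocol,
    n_probe: int = 7,
    probe_span: float = 3.0,
    n_boot: int = 100,
    seed: int = 0,
) -> InferenceResult:
    """Full inference loop: probe r in [r*, probe_span * r*], fit, extrapolate."""
    r_star = protocol.rate_ns_inv
    if r_star <= 0:
        raise ValueError("the ensemble must have been run with resetting (r* > 0)")
    probe = np.linspace(r_star, probe_span * r_star, n_probe)
    tau, se = tau_at_higher_rates(ensemble, protocol, probe, n_boot=n_boot, seed=seed)
    return extrapolate_to_zero(probe, tau, r_star, tau_se_ns=se)


# ---------------------------------------------------------------------------
# direct transit times
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TransitConfig:
    """Two CV surfaces bracketing the transition region.

    ``direction="down"`` counts transits that end below ``lower`` (the
    last-above-``upper`` to first-below-``lower`` segment); ``"up"`` the
    mirror image.
    """

    upper: float
    lower: float
    direction: str = "down"

    def __post_init__(self):
        if not self.upper > self.lower:
            raise ValueError("upper surface must lie above lower surface")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")


def extract_dtt(times, values, config: TransitConfig) -> np.ndarray:
    """Direct transit times of a CV series.

    For each completed transit, the time from the last sample beyond the
    entry surface to the first sample past the exit surface.  Crossings are
    located at stored samples, without sub-step interpolation.  Re-crossings
    of the entry surface before the transit commits discard the earlier
    excursion; after a completed transit the series must return past the
    entry surface before a new transit can be counted.  Returns an empty
    array when no transit completes.
    """
    t = np.asarray(times, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1D arrays")
    if config.direction == "up":
        v = -v
        upper, lower = -config.lower, -config.upper
    else:
        upper, lower = config.upper, config.lower

    ia = np.flatnonzero(v > upper)    # samples beyond the entry surface
    ib = np.flatnonzero(v < lower)    # samples past the exit surface
    dtts = []
    pos = 0
    while True:
        k = np.searchsorted(ia, pos)
        if k == len(ia):
            break
        armed = ia[k]                 # re-armed above the entry surface
        m = np.searchsorted(ib, armed)
        if m == len(ib):
            break
        exit_idx = ib[m]
        q = np.searchsorted(ia, exit_idx) - 1
        dtts.append(t[exit_idx] - t[ia[q]])
        pos = exit_idx + 1
    return np.asarray(dtts)


def mean_dtt(dtt_lists: Sequence[np.ndarray]):
    """Pooled mean DTT and standard error over per-trajectory DTT arrays."""
    allv = np.concatenate([np.asarray(d) for d in dtt_lists]) if dtt_lists else np.empty(0)
    if allv.size == 0:
        return float("nan"), float("nan")
    se = float(np.std(allv, ddof=1) / np.sqrt(allv.size)) if allv.size > 1 else float("inf")
    return float(np.mean(allv)), se
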