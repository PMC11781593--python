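"""Predict MFPTs under informed resetting from reset-free trajectories.

A first-passage process with resetting decomposes, per trajectory, into
M - 1 segments that end in a reset plus one final segment that ends in
first passage, so the FPT is tau_r = sum_j t^j + t^f and the ensemble mean
is

    <tau>_r = (<M> - 1) <t^r> + <t^f>.

Every term on the right can be evaluated from trajectories sampled WITHOUT
resetting by weighting each recorded step with the probability that a
hypothetical resetting clock (rate r, gated by an indicator such as
cv > c) would have fired there.  With the per-step firing probability
p_j = (1 - e^(-r dt)) I_j, the probability a trajectory survives its first
k reset trials is Psi(k) = prod_{j<=k} (1 - p_j); the ensemble survival to
passage gives <M> = 1/<Psi>, and survival-weighted averages of the segment
lengths give <t^f> and <t^r>.  Screening a whole (rate, threshold) grid
costs a few passes over the stored series — no new simulations.

Reset trials are indexed per the simulator's convention: a trial happens at
every retained step strictly before the passage step (a walker that passes
at step n is never reset at step n).  For series stored every S steps the
stride hazard is aggregated, p = 1 - e^(-r S dt), treating the indicator as
constant over the stride.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .dynamics import FPTEnsemble
from .units import FS_PER_NS

__all__ = [
    "ResetFreeSample",
    "PredictionResult",
    "PredictionGrid",
    "per_step_reset_prob",
    "survival",
    "predict_mfpt",
    "screen",
]


def per_step_reset_prob(indicator, rate_ns_inv: float, dt_fs: float):
    """Probability of a reset at one step: (1 - e^(-r dt)) * indicator."""
    if rate_ns_inv < 0 or dt_fs <= 0:
        raise ValueError("need rate >= 0 and dt > 0")
    p = 1.0 - math.exp(-rate_ns_inv / FS_PER_NS * dt_fs)
    return p * np.asarray(indicator, dtype=np.float64)


@dataclasses.dataclass
class ResetFreeSample:
    """Reset-free trajectories as strided CV series plus exact step counts.

    ``cv_series[i]`` holds the CV at steps stride, 2*stride, ... of
    trajectory i, and ``n_steps[i]`` its exact first-passage step count
    (fpt_i = n_steps[i] * dt_fs).
    """

    cv_series: list
    n_steps: np.ndarray
    stride: int
    dt_fs: float

    def __post_init__(self):
        if len(self.cv_series) != len(self.n_steps):
            raise ValueError("one CV series per trajectory required")
        if len(self.cv_series) == 0:
            raise ValueError("empty sample")
        if self.stride < 1 or self.dt_fs <= 0:
            raise ValueError("stride >= 1 and dt > 0 required")
        self.n_steps = np.asarray(self.n_steps, dtype=np.int64)

    @classmethod
    def from_ensemble(cls, ensemble: FPTEnsemble) -> "ResetFreeSample":
        recs = [r for r in ensemble.records if not r.censored]
        if not recs:
            raise ValueError("no uncensored trajectories in the ensemble")
        stride = recs[0].cv_stride
        if stride < 1:
            raise ValueError("ensemble was run without CV recording")
        return cls(
            cv_series=[r.cv_series for r in recs],
            n_steps=np.array([r.n_steps for r in recs], dtype=np.int64),
            stride=stride,
            dt_fs=recs[0].dt_fs,
        )

    @classmethod
    def from_series(cls, series: Sequence[np.ndarray], dt_fs: float, stride: int = 1):
        """Build from raw per-step (or per-stride) CV arrays.

        The last retained point is taken to be the passage step.
        """
        series = [np.asarray(s, dtype=np.float32) for s in series]
        n_steps = np.array([len(s) * stride for s in series], dtype=np.int64)
        return cls(cv_series=series, n_steps=n_steps, stride=stride, dt_fs=dt_fs)

    @classmethod
    def from_colvar_files(cls, paths: Sequence, stride: int = 1):
        """Build from COLVAR-style (time, cv) text files, one per trajectory.

        Each file's time stamps give the sampling interval; ``stride`` is
        the number of integrator steps between stored rows (so the
        underlying time step is interval / stride).
        """
        from .io import read_colvar

        series, n_steps, intervals = [], [], []
        for path in paths:
            t, v = read_colvar(path)
            if len(t) < 2:
                raise ValueError(f"{path}: need at least two samples")
            intervals.append((t[-1] - t[0]) / (len(t) - 1))
            series.append(v.astype(np.float32))
            n_steps.append(len(v) * stride)
        return cls(
            cv_series=series,
            n_steps=np.asarray(n_steps, dtype=np.int64),
            stride=stride,
            dt_fs=float(np.mean(intervals)) / stride,
        )

    @property
    def fpts_ns(self) -> np.ndarray:
        return self.n_steps * self.dt_fs / FS_PER_NS

    @property
    def mfpt_ns(self) -> float:
        return float(np.mean(self.fpts_ns))


def survival(cv_series, rate_ns_inv: float, threshold: Optional[float],
             dt_fs: float = 1.0, stride: int = 1, direction: str = "greater") -> np.ndarray:
    """Psi(k) for k = 1..len(series): survival through the first k reset trials.

    Running product of (1 - p_j) with p_j the gated per-step (or per-stride)
    reset probability; Psi(0) = 1 is implicit.
    """
    cv = np.asarray(cv_series, dtype=np.float64)
    if threshold is None:
        ind = np.ones_like(cv)
    elif direction == "greater":
        ind = (cv > threshold).astype(np.float64)
    else:
        ind = (cv < threshold).astype(np.float64)
    p = 1.0 - math.exp(-rate_ns_inv / FS_PER_NS * dt_fs * stride)
    return np.cumprod(1.0 - p * ind)


@njit(cache=True)
def _survival_terms(cv, n_steps, stride, dt, p_stride, c, use_thresh, greater):
    """(psi_pass, wsum): survival to passage and sum_j t_j Psi(j) p_j (fs)."""
    psi = 1.0
    wsum = 0.0
    for j in range(cv.size):
        step_idx = (j + 1) * stride
        if step_idx >= n_steps:
            break
        if use_thresh:
            cond = cv[j] > c if greater else cv[j] < c
        else:
            cond = True
        if cond:
            wsum += step_idx * dt * psi * p_stride
            psi *= 1.0 - p_stride
    return psi, wsum


@dataclasses.dataclass
class PredictionResult:
    """Predicted MFPT under (rate, threshold) with its Eq-by-Eq components."""

    rate_ns_inv: float
    threshold: Optional[float]
    mfpt_ns: float
    se_ns: float
    survival_mean: float       # <Psi>
    mean_segments: float       # <M> = 1 / <Psi>
    t_final_ns: float          # mean final-segment duration
    t_reset_ns: float          # mean reset-segment duration
    sample_mfpt_ns: float
    ess: float                 # effective no. of trajectories behind <Psi>

    @property
    def speedup(self) -> float:
        return self.sample_mfpt_ns / self.mfpt_ns


def _terms_for_sample(sample: ResetFreeSample, rate_ns_inv, threshold, direction):
    r_fs = rate_ns_inv / FS_PER_NS
    p_stride = 1.0 - math.exp(-r_fs * sample.stride * sample.dt_fs)
    use_thresh = threshold is not None
    c = 0.0 if threshold is None else float(threshold)
    greater = direction == "greater"
    n = len(sample.cv_series)
    psi = np.empty(n)
    wsum = np.empty(n)
    for i in range(n):
        psi[i], wsum[i] = _survival_terms(
            sample.cv_series[i], sample.n_steps[i], sample.stride,
            sample.dt_fs, p_stride, c, use_thresh, greater,
        )
    return psi, wsum


def _assemble(psi, wsum, tau_fs):
    """Combine per-trajectory survival terms into the predicted MFPT (fs)."""
    psi_mean = float(np.mean(psi))
    if psi_mean <= 0.0:
        raise ValueError(
            "every sampled trajectory is certain to be reset at this rate/threshold; "
            "the sample cannot constrain the prediction"
        )
    t_final = float(np.sum(tau_fs * psi) / np.sum(psi))
    denom = np.sum(1.0 - psi)
    t_reset = float(np.sum(wsum) / denom) if denom > 0 else 0.0
    mfpt = (1.0 / psi_mean - 1.0) * t_reset + t_final
    return mfpt, psi_mean, t_final, t_reset


def predict_mfpt(
    sample: ResetFreeSample,
    rate_ns_inv: float,
    threshold: Optional[float],
    direction: str = "greater",
    n_boot: int = 0,
    seed: int = 0,
) -> PredictionResult:
    """Predicted MFPT under ISR at (rate, threshold) from a reset-free sample.

    ``threshold=None`` predicts standard SR.  ``n_boot`` > 0 adds a
    trajectory-level bootstrap standard error (resampling the cached
    per-trajectory survival terms, so it costs nothing extra per draw).
    """
    if rate_ns_inv < 0:
        raise ValueError("rate must be non-negative")
    tau_fs = sample.n_steps.astype(np.float64) * sample.dt_fs
    psi, wsum = _terms_for_sample(sample, rate_ns_inv, threshold, direction)
    mfpt_fs, psi_mean, t_final, t_reset = _assemble(psi, wsum, tau_fs)

    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = psi.size
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                vals.append(_assemble(psi[idx], wsum[idx], tau_fs[idx])[0])
            except ValueError:
                continue
        if len(vals) > 1:
            se = float(np.std(vals, ddof=1)) / FS_PER_NS

    ssum = float(np.sum(psi))
    ess = ssum * ssum / float(np.sum(psi * psi)) if ssum > 0 else 0.0
    return PredictionResult(
        rate_ns_inv=rate_ns_inv,
        threshold=threshold,
        mfpt_ns=mfpt_fs / FS_PER_NS,
        se_ns=se,
        survival_mean=psi_mean,
        mean_segments=1.0 / psi_mean,
        t_final_ns=t_final / FS_PER_NS,
        t_reset_ns=t_reset / FS_PER_NS,
        sample_mfpt_ns=float(np.mean(tau_fs)) / FS_PER_NS,
        ess=ess,
    )


@dataclasses.dataclass
class PredictionGrid:
    """Predicted MFPT/speedup over a (rate, threshold) grid, with the argmax."""

    table: pd.DataFrame
    sample_mfpt_ns: float

    @property
    def best(self) -> pd.Series:
        valid = self.table[self.table["valid"]]
        if valid.empty:
            raise ValueError("no valid cell in the screened grid")
        return valid.loc[valid["speedup"].idxmax()]

    def best_rate(self, threshold) -> float:
        """Highest-speedup rate among valid cells at one threshold."""
        sub = self.table[self.table["valid"]]
        if threshold is None:
            sub = sub[sub["threshold"].isna()]
        else:
            sub = sub[sub["threshold"] == threshold]
        if sub.empty:
            raise ValueError(f"no valid cell at threshold {threshold}")
        return float(sub.loc[sub["speedup"].idxmax(), "rate_ns_inv"])

    def summary(self) -> dict:
        b = self.best
        return {
            "sample_mfpt_ns": self.sample_mfpt_ns,
            "best_rate_ns_inv": float(b["rate_ns_inv"]),
            "best_threshold": None if pd.isna(b["threshold"]) else float(b["threshold"]),
            "best_speedup": float(b["speedup"]),
            "best_mfpt_ns": float(b["mfpt_ns"]),
        }


def screen(
    sample: ResetFreeSample,
    rates_ns_inv: Sequence[float],
    thresholds: Sequence[Optional[float]],
    direction: str = "greater",
    n_boot: int = 0,
    seed: int = 0,
    min_ess: float = 5.0,
) -> PredictionGrid:
    """Evaluate the predictor on the full (rate, threshold) grid.

    Cells where the sample cannot support the prediction — every trajectory
    certain to reset, or fewer than ``min_ess`` effective trajectories left
    carrying survival weight — are marked invalid rather than aborting the
    scan or reporting an unsupported number.  A ``None`` threshold screens
    standard SR.
    """
    if len(rates_ns_inv) == 0 or len(thresholds) == 0:
        raise ValueError("rate and threshold grids must be non-empty")
    # small samples cannot clear an absolute support bar; scale it down
    ess_bar = min(min_ess, 0.5 * len(sample.cv_series))
    rows = []
    for c in thresholds:
        for r in rates_ns_inv:
            try:
                res = predict_mfpt(sample, r, c, direction, n_boot=n_boot, seed=seed)
                rows.append(
                    dict(
                        rate_ns_inv=r,
                        threshold=np.nan if c is None else c,
                        mfpt_ns=res.mfpt_ns,
                        se_ns=res.se_ns,
                        speedup=res.speedup,
                        mean_segments=res.mean_segments,
                        survival=res.survival_mean,
                        ess=res.ess,
                        valid=bool(res.ess >= ess_bar or r == 0.0),
                    )
                )
            except ValueError:
                rows.append(
                    dict(
                        rate_ns_inv=r,
                        threshold=np.nan if c is None else c,
                        mfpt_ns=np.nan, se_ns=np.nan, speedup=np.nan,
                        mean_segments=np.nan, survival=np.nan, ess=0.0,
                        valid=False,
                    )
                )
    table = pd.DataFrame(rows)
    sample_mfpt = float(np.mean(sample.n_steps * sample.dt_fs)) / FS_PER_NS
    return PredictionGrid(table=table, sample_mfpt_ns=sample_mfpt)
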