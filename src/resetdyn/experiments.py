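"""Scripted reproduction of the model-system studies, plus fast test fixtures.

Every study runs on the modified Faradjian-Elber surface with the standard
settings (300 K, friction 0.01 fs^-1, dt 1 fs, mass 40 g/mol, start at the
(3, 0) minimum, first passage at x < -1) unless the experiment spec
overrides them.  Ensemble sizes default to desk-scale reductions of the
original 10^3-10^4-trajectory studies; means are unchanged by the
reduction, error bars widen as 1/sqrt(n).

The fixture generator builds a scaled-down surface (lower ridge and saddle)
whose unbiased MFPT sits in a configurable band well under a nanosecond, so
that whole property-test suites run in seconds while preserving the
phenomenology that matters: a heavy-tailed FPT distribution, the
plateauing-speedup class of thresholds beyond the start point, and the
unimodal class inside it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import FPTEnsemble, SimConfig, StopCondition, run_until_fpt
from .metad import MetaDEngine
from .potential import PotentialSurface, double_well_1d, modified_faradjian_elber
from .predictor import PredictionGrid, ResetFreeSample, predict_mfpt, screen
from .resetting import ResetProtocol, speedup
from .inference import TransitConfig, extract_dtt, infer_unbiased_mfpt, mean_dtt

__all__ = [
    "START",
    "STOP",
    "ExperimentSpec",
    "FixtureSpec",
    "Fixture",
    "make_config",
    "baseline_ensemble",
    "accelerated_ensemble",
    "metad_ensemble",
    "screen_optimal_rate",
    "generate_fixture",
    "double_well_fixture",
    "run_experiment",
]

START = (3.0, 0.0)
STOP = StopCondition(threshold=-1.0, direction="below")

DEFAULT_RATES = (5.0, 10.0, 100.0, 1000.0, 1.0e4, 1.0e5)
DEFAULT_THRESHOLDS = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_THETAS = (0.0, 8.0, 16.0, 24.0)


def make_config(seed: int, max_steps: int = 400_000_000, **overrides) -> SimConfig:
    """Standard simulation settings with a given seed."""
    return SimConfig(seed=seed, max_steps=max_steps, **overrides)


def baseline_ensemble(
    surface: PotentialSurface,
    n: int,
    seed: int,
    record_stride: int = 0,
    config: Optional[SimConfig] = None,
    start=START,
    stop=STOP,
) -> FPTEnsemble:
    """Unbiased ensemble from the starting minimum to first passage."""
    cfg = config if config is not None else make_config(seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    return run_until_fpt(surface, cfg, stop, n, start=start, record_stride=record_stride)


def accelerated_ensemble(
    surface: PotentialSurface,
    protocol: ResetProtocol,
    n: int,
    seed: int,
    metad: Optional[MetaDEngine] = None,
    record_stride: int = 0,
    config: Optional[SimConfig] = None,
    start=START,
    stop=STOP,
) -> FPTEnsemble:
    """Ensemble with resetting (and optionally MetaD) layered on the dynamics."""
    cfg = config if config is not None else make_config(seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    return run_until_fpt(
        surface, cfg, stop, n, start=start, protocol=protocol, metad=metad,
        record_stride=record_stride,
    )


def metad_ensemble(
    surface: PotentialSurface,
    n: int,
    seed: int,
    theta_deg: float = 0.0,
    pace: int = 100,
    record_stride: int = 0,
    config: Optional[SimConfig] = None,
    start=START,
    stop=STOP,
    **metad_kwargs,
) -> FPTEnsemble:
    """Well-tempered MetaD ensemble without resetting."""
    engine = MetaDEngine(pace=pace, theta_deg=theta_deg, **metad_kwargs)
    cfg = config if config is not None else make_config(seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    return run_until_fpt(
        surface, cfg, stop, n, start=start, metad=engine, record_stride=record_stride,
    )


def screen_optimal_rate(
    sample: ResetFreeSample,
    threshold: Optional[float],
    rates: Sequence[float] = DEFAULT_RATES,
    direction: str = "greater",
) -> float:
    """Predictor-screened rate with the highest predicted speedup.

    Uses the plain argmax over every cell the sample defines (the original
    screening procedure); interactive users wanting the support-guarded
    variant should call :func:`resetdyn.predictor.screen` directly.
    """
    grid = screen(sample, list(rates), [threshold], direction=direction, min_ess=0.0)
    return grid.best_rate(threshold)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FixtureSpec:
    """A fast-converging scaled surface for tests.

    ``ridge_kt`` and ``saddle_kt`` shrink the two barriers of the standard
    surface (12 and 3 k_BT) while keeping its geometry; the generator
    verifies the unbiased MFPT lands in ``mfpt_band_ns`` and rescales the
    barriers if it does not.
    """

    ridge_kt: float = 3.0
    saddle_kt: float = 1.0
    temperature: float = 300.0
    mfpt_band_ns: tuple = (0.001, 0.06)
    n_baseline: int = 300
    record_stride: int = 2
    max_retries: int = 3


@dataclasses.dataclass
class Fixture:
    surface: PotentialSurface
    baseline: FPTEnsemble
    sample: ResetFreeSample
    config: SimConfig

    @property
    def mfpt_ns(self) -> float:
        return self.baseline.mfpt_ns


def fixture_surface(ridge_kt: float = 3.0, saddle_kt: float = 1.0) -> PotentialSurface:
    """Scaled surface: lower barriers, wider channel, tighter confinement."""
    return modified_faradjian_elber(
        a2=ridge_kt, b=1.0 - saddle_kt / ridge_kt, sigma2=1.5, yscale=0.5
    )


def generate_fixture(spec: FixtureSpec = FixtureSpec(), seed: int = 0) -> Fixture:
    """Build the fast surface and its cached unbiased baseline ensemble."""
    ridge, saddle = spec.ridge_kt, spec.saddle_kt
    for attempt in range(spec.max_retries + 1):
        surface = fixture_surface(ridge, saddle)
        cfg = make_config(seed, temperature=spec.temperature, max_steps=20_000_000)
        ens = run_until_fpt(
            surface, cfg, STOP, spec.n_baseline, start=START,
            record_stride=spec.record_stride,
        )
        lo, hi = spec.mfpt_band_ns
        if lo <= ens.mfpt_ns <= hi:
            return Fixture(surface, ens, ResetFreeSample.from_ensemble(ens), cfg)
        scale = 0.75 if ens.mfpt_ns > hi else 1.3
        ridge *= scale
        saddle *= scale
    raise RuntimeError(
        f"fixture MFPT {ens.mfpt_ns:.4f} ns outside band {spec.mfpt_band_ns} "
        f"after {spec.max_retries} barrier adjustments"
    )


def double_well_fixture(barrier_kt: float = 3.0):
    """Quartic double well whose FPTs standard SR cannot accelerate.

    Starting in one minimum, escape over a single barrier is nearly
    exponential (coefficient of variation about 1), so SR is neutral at
    best, while resetting only from beyond the start (threshold at the
    minimum) still helps.
    """
    return double_well_1d(barrier_kt=barrier_kt, half_separation=3.0, transverse_k=0.5)


# ---------------------------------------------------------------------------
# experiment specs and runner
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentSpec:
    """One reproducible study; see ``run_experiment`` for the ids."""

    experiment_id: str
    seed: int = 0
    n_baseline: int = 200
    n_accel: int = 300
    n_metad: int = 300
    rates: Sequence[float] = DEFAULT_RATES
    thresholds: Sequence[Optional[float]] = DEFAULT_THRESHOLDS
    thetas: Sequence[float] = DEFAULT_THETAS
    record_stride: int = 20
    out_dir: Optional[str] = None
    make_plots: bool = False
    surface_config: Optional[dict] = None
    temperature: float = 300.0
    max_steps: int = 400_000_000

    def surface(self) -> PotentialSurface:
        if self.surface_config is None:
            return modified_faradjian_elber()
        from .potential import surface_from_config

        return surface_from_config(self.surface_config)

    def config(self, seed_offset: int = 0) -> SimConfig:
        return make_config(
            self.seed + seed_offset, temperature=self.temperature, max_steps=self.max_steps
        )


def _speedup_row(baseline, ens, **labels):
    s, se = speedup(baseline, ens)
    row = dict(labels)
    row.update(
        mfpt_ns=ens.mfpt_ns, sem_ns=ens.sem_ns, speedup=s, speedup_se=se,
        mean_resets=ens.mean_resets, n=len(ens), n_censored=ens.n_censored,
    )
    return row


def _check_censoring(ens, label):
    frac = ens.n_censored / len(ens)
    if frac > 0.01:
        warnings.warn(f"{label}: censored fraction {frac:.1%} exceeds 1%", stacklevel=2)


def _fig1b(spec: ExperimentSpec):
    """Speedup vs resetting rate for standard SR and ISR at each threshold."""
    surface = spec.surface()
    baseline = baseline_ensemble(
        surface, spec.n_baseline, spec.seed, record_stride=spec.record_stride,
        config=spec.config(),
    )
    _check_censoring(baseline, "baseline")
    rows = []
    methods = [("SR", None)] + [("ISR", c) for c in spec.thresholds if c is not None]
    for k, (method, c) in enumerate(methods):
        for j, r in enumerate(spec.rates):
            proto = ResetProtocol(rate_ns_inv=r, threshold=c)
            ens = accelerated_ensemble(
                surface, proto, spec.n_accel, spec.seed + 1000 + 97 * k + j,
                config=spec.config(),
            )
            _check_censoring(ens, f"{method} c={c} r={r}")
            rows.append(_speedup_row(baseline, ens, method=method, rate_ns_inv=r, threshold=c))
    table = pd.DataFrame(rows)
    return {"baseline": baseline, "table": table}


def _fig2(spec: ExperimentSpec):
    """Maximal speedup vs CV quality (rotation angle) for four methods."""
    surface = spec.surface()
    baseline = baseline_ensemble(
        surface, spec.n_baseline, spec.seed, record_stride=spec.record_stride,
        config=spec.config(),
    )
    plateau_rate = max(spec.rates)
    rows = []
    for k, theta in enumerate(spec.thetas):
        seed = spec.seed + 2000 + 17 * k
        # ISR alone: threshold at the start point is in the plateau class
        isr = accelerated_ensemble(
            surface, ResetProtocol(plateau_rate, threshold=3.0, theta_deg=theta),
            spec.n_accel, seed, config=spec.config(),
        )
        rows.append(_speedup_row(baseline, isr, method="ISR", theta_deg=theta))
        # MetaD alone, recording its CV for rate screening
        md = metad_ensemble(
            surface, spec.n_metad, seed + 1, theta_deg=theta,
            record_stride=spec.record_stride, config=spec.config(),
        )
        rows.append(_speedup_row(baseline, md, method="MetaD", theta_deg=theta))
        md_sample = ResetFreeSample.from_ensemble(md)
        r_sr = screen_optimal_rate(md_sample, None, spec.rates)
        md_sr = accelerated_ensemble(
            surface, ResetProtocol(r_sr, threshold=None, theta_deg=theta),
            spec.n_metad, seed + 2, metad=MetaDEngine(theta_deg=theta), config=spec.config(),
        )
        rows.append(
            _speedup_row(baseline, md_sr, method="MetaD+SR", theta_deg=theta, rate_ns_inv=r_sr)
        )
        r_isr = screen_optimal_rate(md_sample, 3.0, spec.rates)
        md_isr = accelerated_ensemble(
            surface, ResetProtocol(r_isr, threshold=3.0, theta_deg=theta),
            spec.n_metad, seed + 3, metad=MetaDEngine(theta_deg=theta), config=spec.config(),
        )
        rows.append(
            _speedup_row(baseline, md_isr, method="MetaD+ISR", theta_deg=theta, rate_ns_inv=r_isr)
        )
    return {"baseline": baseline, "table": pd.DataFrame(rows)}


def _fig3(spec: ExperimentSpec):
    """Predictor screening of speedups over the full (rate, threshold) grid."""
    surface = spec.surface()
    baseline = baseline_ensemble(
        surface, spec.n_baseline, spec.seed, record_stride=spec.record_stride,
        config=spec.config(),
    )
    sample = ResetFreeSample.from_ensemble(baseline)
    grid = screen(sample, list(spec.rates), [None] + list(spec.thresholds), n_boot=50)
    return {"baseline": baseline, "grid": grid, "table": grid.table}


def _fig4(spec: ExperimentSpec):
    """Unbiased-MFPT inference from ISR ensembles at increasing r*."""
    surface = spec.surface()
    baseline = baseline_ensemble(surface, spec.n_baseline, spec.seed, config=spec.config())
    rows = []
    protos = []
    for c in spec.thresholds:
        for r in spec.rates:
            protos.append(ResetProtocol(rate_ns_inv=r, threshold=c))
    for k, proto in enumerate(protos):
        ens = accelerated_ensemble(
            surface, proto, spec.n_accel, spec.seed + 3000 + k,
            record_stride=spec.record_stride, config=spec.config(),
        )
        s, s_se = speedup(baseline, ens)
        try:
            inf = infer_unbiased_mfpt(ens, proto, seed=spec.seed + k)
            mfpt0, se0 = inf.mfpt_ns, inf.se_ns
            fold = inf.fold_error(baseline.mfpt_ns)
        except ValueError:
            mfpt0 = se0 = fold = float("nan")
        rows.append(
            dict(
                threshold=proto.threshold, r_star_ns_inv=proto.rate_ns_inv,
                speedup=s, speedup_se=s_se, inferred_mfpt_ns=mfpt0,
                inferred_se_ns=se0, reference_mfpt_ns=baseline.mfpt_ns, fold_error=fold,
            )
        )
    return {"baseline": baseline, "table": pd.DataFrame(rows)}


def _dtt_toy(spec: ExperimentSpec):
    """Mean direct transit time vs MetaD pace on the model surface.

    Transits are measured on the recorded x series between the surfaces
    x = +1 and x = -1 bracketing the barrier.
    """
    surface = spec.surface()
    tcfg = TransitConfig(upper=1.0, lower=-1.0)
    stride = max(1, min(spec.record_stride, 5))
    baseline = baseline_ensemble(
        surface, spec.n_baseline, spec.seed, record_stride=stride, config=spec.config()
    )
    rows = []

    def add_row(ens, label, pace):
        dtts = [
            extract_dtt(np.arange(1, r.cv_series.size + 1) * stride * r.dt_fs, r.cv_series, tcfg)
            for r in ens.records
            if not r.censored
        ]
        m, se = mean_dtt(dtts)
        s, s_se = speedup(baseline, ens) if ens is not baseline else (1.0, 0.0)
        rows.append(
            dict(
                method=label, pace=pace, mean_dtt_fs=m, dtt_se_fs=se,
                n_transits=int(sum(len(d) for d in dtts)), speedup=s, speedup_se=s_se,
            )
        )

    add_row(baseline, "unbiased", 0)
    for k, pace in enumerate((50, 100, 200, 500)):
        md = metad_ensemble(
            surface, spec.n_metad, spec.seed + 4000 + k, pace=pace,
            record_stride=stride, config=spec.config(),
        )
        add_row(md, "MetaD", pace)
    return {"baseline": baseline, "table": pd.DataFrame(rows)}


_RUNNERS = {
    "fig1b": _fig1b,
    "fig2": _fig2,
    "fig3": _fig3,
    "fig4": _fig4,
    "dtt_toy": _dtt_toy,
}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Run one named study; returns its tables and writes CSV + manifest.

    Deterministic for a fixed spec (including the seed): the per-ensemble
    seeds are fixed offsets of ``spec.seed``.
    """
    if spec.experiment_id not in _RUNNERS:
        raise ValueError(f"unknown experiment id {spec.experiment_id!r}; "
                         f"choose from {sorted(_RUNNERS)}")
    result = _RUNNERS[spec.experiment_id](spec)
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result["table"].to_csv(out / f"{spec.experiment_id}.csv", index=False)
        manifest = dataclasses.asdict(spec)
        manifest["rates"] = list(map(float, spec.rates))
        manifest["thresholds"] = [None if c is None else float(c) for c in spec.thresholds]
        manifest["thetas"] = list(map(float, spec.thetas))
        manifest["baseline_mfpt_ns"] = result["baseline"].mfpt_ns
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if spec.make_plots:
            _plot(spec, result, out)
    return result


def _plot(spec, result, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result["table"]
    fig, ax = plt.subplots(figsize=(5, 4))
    if spec.experiment_id in ("fig1b", "fig3"):
        key = "threshold" if "threshold" in table else None
        for c, sub in table.groupby(table["threshold"].fillna(-99)):
            label = "SR" if c == -99 else f"c={c:g}"
            ax.plot(sub["rate_ns_inv"], sub["speedup"], "o--", label=label)
        ax.set_xscale("log")
        ax.set_xlabel("resetting rate (1/ns)")
        ax.set_ylabel("speedup")
    elif spec.experiment_id == "fig2":
        for m, sub in table.groupby("method"):
            ax.plot(sub["theta_deg"], sub["speedup"], "o-", label=m)
        ax.set_xlabel("CV rotation (deg)")
        ax.set_ylabel("max speedup")
        ax.set_yscale("log")
    elif spec.experiment_id == "fig4":
        ax.errorbar(table["speedup"], table["inferred_mfpt_ns"], yerr=table["inferred_se_ns"], fmt="o")
        ax.axhline(table["reference_mfpt_ns"].iloc[0], color="k", ls="--")
        ax.set_xlabel("speedup")
        ax.set_ylabel("inferred unbiased MFPT (ns)")
    else:
        ax.errorbar(table["pace"], table["mean_dtt_fs"], yerr=table["dtt_se_fs"], fmt="o")
        ax.set_xlabel("MetaD pace (steps)")
        ax.set_ylabel("mean DTT (fs)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / f"{spec.experiment_id}.png", dpi=150)
    plt.close(fig)
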