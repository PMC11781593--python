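"""Kinetics inference: rate extrapolation and direct transit times."""

import math

import numpy as np
import pytest

from resetdyn.experiments import accelerated_ensemble, metad_ensemble
from resetdyn.inference import (
    TransitConfig,
    extract_dtt,
    extrapolate_to_zero,
    infer_unbiased_mfpt,
    mean_dtt,
    tau_at_higher_rates,
)
from resetdyn.resetting import ResetProtocol
from resetdyn.theory import drift_diffusion_mfpt_under_reset


# ---------------------------------------------------------------------------
# extrapolation to r = 0
# ---------------------------------------------------------------------------

def test_constant_tau_extrapolates_to_itself():
    r = np.linspace(1.0, 3.0, 6)
    res = extrapolate_to_zero(r, np.full(6, 4.2), r_star_ns_inv=1.0)
    assert res.mfpt_ns == pytest.approx(4.2, rel=1e-8)


def test_extrapolation_recovers_drift_diffusion_closed_form():
    """Probe MFPTs synthesised from the solvable drift-diffusion model
    extrapolate back to its known r = 0 value x0/v."""
    x0, v, D = 4.0, 0.5, 1.0
    tau0 = x0 / v
    r_star = 0.05
    probe = np.linspace(r_star, 3 * r_star, 7)
    tau = drift_diffusion_mfpt_under_reset(x0, v, D, probe)
    res = extrapolate_to_zero(probe, tau, r_star)
    assert res.mfpt_ns == pytest.approx(tau0, rel=0.05)


def test_extrapolation_needs_enough_points():
    with pytest.raises(ValueError):
        extrapolate_to_zero([1.0, 2.0], [3.0, 4.0], 1.0)


def test_probe_at_rstar_returns_ensemble_mfpt(fast_fixture):
    proto = ResetProtocol(500.0, threshold=3.0)
    ens = accelerated_ensemble(
        fast_fixture.surface, proto, 120, seed=50, record_stride=2,
        config=fast_fixture.config,
    )
    tau, _ = tau_at_higher_rates(ens, proto, [proto.rate_ns_inv], n_boot=0)
    assert tau[0] == pytest.approx(ens.mfpt_ns, rel=1e-9)
    with pytest.raises(ValueError):
        tau_at_higher_rates(ens, proto, [100.0])


def test_probe_rates_agree_with_direct_simulation(fast_fixture):
    """Superposed-clock reweighting of an r* ensemble predicts the MFPT the
    simulator measures when actually run at the probe rates."""
    r_star = 300.0
    proto = ResetProtocol(r_star, threshold=3.0)
    ens = accelerated_ensemble(
        fast_fixture.surface, proto, 400, seed=51, record_stride=2,
        config=fast_fixture.config,
    )
    probes = [900.0, 2500.0]
    tau, se = tau_at_higher_rates(ens, proto, probes, n_boot=200, seed=1)
    for r_probe, tau_p, se_p in zip(probes, tau, se):
        direct = accelerated_ensemble(
            fast_fixture.surface, ResetProtocol(r_probe, threshold=3.0),
            400, seed=52 + int(r_probe), config=fast_fixture.config,
        )
        err = math.hypot(se_p, direct.sem_ns)
        assert abs(tau_p - direct.mfpt_ns) < 3 * err


def test_full_inference_loop_recovers_unbiased_mfpt(fast_fixture):
    """Simulate with ISR, probe higher rates, extrapolate to r = 0; the
    result lands within a factor two of the directly simulated MFPT."""
    proto = ResetProtocol(300.0, threshold=3.0)
    ens = accelerated_ensemble(
        fast_fixture.surface, proto, 400, seed=53, record_stride=2,
        config=fast_fixture.config,
    )
    res = infer_unbiased_mfpt(ens, proto, seed=7)
    assert res.mfpt_ns > 0
    assert res.fold_error(fast_fixture.mfpt_ns) < 2.0


# ---------------------------------------------------------------------------
# direct transit times
# ---------------------------------------------------------------------------

CFG = TransitConfig(upper=2.35, lower=1.0)


def test_monotone_crossing_single_dtt():
    t = np.linspace(0.0, 10.0, 301)
    v = 3.0 - 0.3 * t
    d = extract_dtt(t, v, CFG)
    assert d.size == 1
    t_upper = t[np.flatnonzero(v > 2.35)[-1]]
    t_lower = t[np.flatnonzero(v < 1.0)[0]]
    assert d[0] == pytest.approx(t_lower - t_upper)


def test_recrossing_counts_only_final_excursion():
    v = np.array([3.0, 2.0, 3.0, 2.0, 1.5, 2.5, 1.2, 0.5])
    t = np.arange(8.0)
    d = extract_dtt(t, v, CFG)
    assert d.tolist() == [7.0 - 5.0]


def test_multiple_transits_require_rearming():
    v = np.array([3.0, 1.5, 0.5, 0.7, 3.0, 0.8])
    t = np.arange(6.0)
    d = extract_dtt(t, v, CFG)
    assert d.tolist() == [2.0, 1.0]


def test_no_transit_returns_empty():
    t = np.arange(5.0)
    assert extract_dtt(t, np.full(5, 1.5), CFG).size == 0
    m, se = mean_dtt([])
    assert math.isnan(m)


def test_upward_direction_mirrors_downward():
    v = np.array([0.5, 1.2, 2.5, 1.5, 2.0, 3.0])
    t = np.arange(6.0)
    up = extract_dtt(t, v, TransitConfig(upper=2.35, lower=1.0, direction="up"))
    down = extract_dtt(t, -v, TransitConfig(upper=-1.0, lower=-2.35))
    assert np.array_equal(up, down)
    assert up.size == 1


def test_transit_config_validation():
    with pytest.raises(ValueError):
        TransitConfig(upper=1.0, lower=2.0)


def test_dtt_never_exceeds_fpt(fast_fixture):
    """A transit is a sub-segment of its trajectory."""
    cfg = TransitConfig(upper=1.0, lower=-1.0)
    for rec in fast_fixture.baseline.records[:100]:
        if rec.censored:
            continue
        t = np.arange(1, rec.cv_series.size + 1) * rec.cv_stride * rec.dt_fs
        d = extract_dtt(t, rec.cv_series, cfg)
        assert np.all(d <= rec.n_steps * rec.dt_fs + 1e-9)


def test_mean_dtt_insensitive_to_bias_deposition_pace(fast_fixture):
    """MetaD hill pace changes the FPT speedup strongly but leaves the mean
    direct transit time unchanged within sampling error.

    Hills are kept small against the barrier (as in the full-scale system)
    so the bias steers which trajectories cross, not how fast the committed
    transit itself moves.
    """
    cfg = TransitConfig(upper=1.0, lower=-1.0)

    def pooled(pace, seed):
        ens = metad_ensemble(
            fast_fixture.surface, 200, seed, pace=pace, height_kt=0.1,
            record_stride=2, config=fast_fixture.config,
        )
        dtts = [
            extract_dtt(
                np.arange(1, r.cv_series.size + 1) * r.cv_stride * r.dt_fs, r.cv_series, cfg
            )
            for r in ens.records if not r.censored
        ]
        return mean_dtt(dtts)

    m_fast, se_fast = pooled(100, 60)
    m_slow, se_slow = pooled(1000, 61)
    err = math.hypot(se_fast, se_slow)
    assert abs(m_fast - m_slow) < 3 * err
    # and both agree with the unbiased mean DTT
    unbiased = [
        extract_dtt(
            np.arange(1, r.cv_series.size + 1) * r.cv_stride * r.dt_fs, r.cv_series, cfg
        )
        for r in fast_fixture.baseline.records
    ]
    m0, se0 = mean_dtt(unbiased)
    assert abs(m_fast - m0) < 3 * math.hypot(se_fast, se0)
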