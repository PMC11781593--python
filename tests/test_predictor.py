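"""Trajectory-reweighting predictor: survival math, oracles, consistency."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resetdyn.dynamics import FPTEnsemble
from resetdyn.experiments import START, STOP, accelerated_ensemble
from resetdyn.predictor import (
    ResetFreeSample,
    per_step_reset_prob,
    predict_mfpt,
    screen,
    survival,
)
from resetdyn.resetting import ResetProtocol, speedup
from resetdyn.units import FS_PER_NS


def rate_for_p(p, dt_fs=1.0, stride=1):
    """Resetting rate (1/ns) whose per-stride firing probability is p."""
    return -math.log(1.0 - p) / (dt_fs * stride) * FS_PER_NS


# ---------------------------------------------------------------------------
# survival function
# ---------------------------------------------------------------------------

def test_per_step_reset_prob_closed_forms():
    assert per_step_reset_prob(1, 0.0, 1.0) == 0.0
    assert per_step_reset_prob(0, 5000.0, 1.0) == 0.0
    r_half = math.log(2.0) * FS_PER_NS  # r*dt = ln 2
    assert per_step_reset_prob(1, r_half, 1.0) == pytest.approx(0.5)


def test_survival_hand_series():
    """Indicators (0,1,1,0,1) at p=0.1 give Psi = (1, .9, .81, .81, .729)."""
    cv = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
    psi = survival(cv, rate_for_p(0.1), threshold=0.5, dt_fs=1.0)
    assert np.allclose(psi, [1.0, 0.9, 0.81, 0.81, 0.729], rtol=1e-12)


def test_survival_limits():
    cv = np.zeros(8)
    assert np.all(survival(cv, 1e4, threshold=0.5) == 1.0)
    cv1 = np.ones(6)
    r = 2000.0
    psi = survival(cv1, r, threshold=None)
    k = np.arange(1, 7)
    assert np.allclose(psi, np.exp(-r / FS_PER_NS * k), rtol=1e-12)


@settings(deadline=None, max_examples=60)
@given(
    bits=st.lists(st.integers(0, 1), min_size=1, max_size=30),
    p=st.floats(0.01, 0.95),
)
def test_survival_matches_explicit_product(bits, p):
    cv = np.array(bits, dtype=float)
    psi = survival(cv, rate_for_p(p), threshold=0.5, dt_fs=1.0)
    acc, expected = 1.0, []
    for b in bits:
        acc *= 1.0 - p * b
        expected.append(acc)
    assert np.allclose(psi, expected, rtol=1e-10)


# ---------------------------------------------------------------------------
# predicted MFPT: exact small-instance oracle
# ---------------------------------------------------------------------------

def enumeration_oracle(indicator_lists, p, dt_fs=1.0):
    """Exact MFPT under resetting for the renewal process whose segments are
    drawn uniformly from the given trajectories.

    Enumerates the full tree of reset-trial outcomes (trials happen at every
    step before the passage step where the indicator is 1, each firing with
    probability p) and solves m = E[segment] + P(reset) * m.
    """
    outcomes = []  # (probability, length_in_steps, ends_in_reset)
    n_traj = len(indicator_lists)
    for ind in indicator_lists:
        n = len(ind)
        trial_steps = [j for j in range(1, n) if ind[j - 1] == 1]
        for bits in itertools.product([0, 1], repeat=len(trial_steps)):
            # full realization of every trial; the outcome is decided by the
            # first trial that fired
            prob = 1.0
            for bit in bits:
                prob *= p if bit else (1.0 - p)
            fired = next(
                (s for s, bit in zip(trial_steps, bits) if bit), None
            )
            if fired is not None:
                outcomes.append((prob / n_traj, fired, True))
            else:
                outcomes.append((prob / n_traj, n, False))
    e_len = sum(pr * ln for pr, ln, _ in outcomes) * dt_fs
    p_reset = sum(pr for pr, _, reset in outcomes if reset)
    return e_len / (1.0 - p_reset)


def test_predictor_matches_enumeration_oracle():
    """Exhaustive outcome-tree enumeration equals the survival-weighted
    estimate on hand-sized trajectories."""
    cases = [
        ([[1, 1, 1], [0, 1, 0]], 0.5),
        ([[1, 0, 1, 1], [1, 1, 1, 1, 1]], 0.3),
        ([[0, 0, 0], [1, 1]], 0.7),
        ([[1], [0, 1, 1, 0, 1, 1, 1]], 0.2),
    ]
    for indicators, p in cases:
        oracle = enumeration_oracle(indicators, p)
        sample = ResetFreeSample.from_series(
            [np.array(i, dtype=np.float32) for i in indicators], dt_fs=1.0
        )
        res = predict_mfpt(sample, rate_for_p(p), threshold=0.5)
        assert res.mfpt_ns * FS_PER_NS == pytest.approx(oracle, rel=1e-10)


def test_zero_rate_returns_sample_mean():
    rng = np.random.default_rng(0)
    series = [rng.normal(size=n).astype(np.float32) for n in (5, 17, 40)]
    sample = ResetFreeSample.from_series(series, dt_fs=2.0)
    res = predict_mfpt(sample, 0.0, threshold=0.0)
    assert res.mfpt_ns == pytest.approx(sample.mfpt_ns, rel=1e-12)
    assert res.mean_segments == pytest.approx(1.0)


def test_survival_mean_monotone_in_rate_and_threshold(fast_fixture):
    sample = fast_fixture.sample
    rates = [10.0, 100.0, 1000.0]
    psis = [predict_mfpt(sample, r, threshold=3.0).survival_mean for r in rates]
    assert psis[0] >= psis[1] >= psis[2]
    # lowering the threshold (direction 'greater') can only add reset events
    psi_by_c = [predict_mfpt(sample, 100.0, threshold=c).survival_mean for c in (4.0, 3.0, 2.0)]
    assert psi_by_c[0] >= psi_by_c[1] >= psi_by_c[2]


def test_aggressive_protocol_raises():
    sample = ResetFreeSample.from_series([np.ones(400, dtype=np.float32)], dt_fs=1.0)
    with pytest.raises(ValueError, match="certain to be reset"):
        predict_mfpt(sample, 5e7, threshold=0.5)


# ---------------------------------------------------------------------------
# consistency with direct simulation
# ---------------------------------------------------------------------------

def test_eq1_decomposition_is_exact_per_trajectory(fast_fixture):
    """Segment durations of a resetting run recompose to the recorded FPT."""
    proto = ResetProtocol(rate_ns_inv=2000.0, threshold=3.0)
    ens = accelerated_ensemble(fast_fixture.surface, proto, 40, seed=5,
                               config=fast_fixture.config)
    checked = 0
    for rec in ens.records:
        if rec.censored or rec.reset_count == 0:
            continue
        bounds = np.concatenate([[0], rec.reset_steps, [rec.n_steps]])
        segs = np.diff(bounds)
        m = rec.reset_count + 1
        t_reset_mean = segs[:-1].mean()
        total = (m - 1) * t_reset_mean + segs[-1]
        assert total * rec.dt_fs == pytest.approx(rec.fpt_ns * FS_PER_NS, rel=1e-12)
        checked += 1
    assert checked > 5


def test_prediction_agrees_with_direct_simulation(fast_fixture):
    """Reset-free reweighting reproduces the simulated ISR MFPT within
    3 combined standard errors."""
    r, c = 500.0, 3.0
    res = predict_mfpt(fast_fixture.sample, r, threshold=c, n_boot=200, seed=1)
    proto = ResetProtocol(rate_ns_inv=r, threshold=c)
    ens = accelerated_ensemble(fast_fixture.surface, proto, 400, seed=21,
                               config=fast_fixture.config)
    err = math.hypot(res.se_ns, ens.sem_ns)
    assert abs(res.mfpt_ns - ens.mfpt_ns) < 3.0 * err


def test_standard_sr_prediction_agrees_with_simulation(fast_fixture):
    r = 200.0
    res = predict_mfpt(fast_fixture.sample, r, threshold=None, n_boot=200, seed=2)
    ens = accelerated_ensemble(
        fast_fixture.surface, ResetProtocol(rate_ns_inv=r), 400, seed=22,
        config=fast_fixture.config,
    )
    err = math.hypot(res.se_ns, ens.sem_ns)
    assert abs(res.mfpt_ns - ens.mfpt_ns) < 3.0 * err


def test_stride_aggregation_consistency(fast_fixture):
    """Predictions from coarser-strided storage agree closely with the
    fine-strided ones when the per-stride hazard stays small."""
    fine = fast_fixture.sample
    coarse = ResetFreeSample(
        cv_series=[s[2::3] for s in fine.cv_series],
        n_steps=fine.n_steps,
        stride=fine.stride * 3,
        dt_fs=fine.dt_fs,
    )
    for r in (100.0, 1000.0):
        a = predict_mfpt(fine, r, threshold=3.0).mfpt_ns
        b = predict_mfpt(coarse, r, threshold=3.0).mfpt_ns
        assert b == pytest.approx(a, rel=0.08)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_degenerate_zero_rate():
    rng = np.random.default_rng(4)
    sample = ResetFreeSample.from_series(
        [rng.normal(size=50).astype(np.float32) for _ in range(10)], dt_fs=1.0
    )
    grid = screen(sample, [0.0], [None, 1.0])
    assert np.allclose(grid.table["speedup"], 1.0)


def test_screen_marks_invalid_cells_and_reports_argmax(fast_fixture):
    sample = ResetFreeSample.from_series([np.ones(500, dtype=np.float32)], dt_fs=1.0)
    grid = screen(sample, [10.0, 5e7], [0.5])
    assert grid.table["valid"].tolist() == [True, False]

    grid2 = screen(fast_fixture.sample, [100.0, 1000.0, 10000.0], [2.0, 3.0])
    best = grid2.best
    assert best["speedup"] == grid2.table[grid2.table["valid"]]["speedup"].max()
    assert grid2.best_rate(3.0) in (100.0, 1000.0, 10000.0)
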