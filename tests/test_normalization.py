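"""Torque normalization: objective, optimizer, SO baseline, metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stsnorm as s
from stsnorm.errors import DegenerateInputError, ValidationError
from stsnorm.muscles import MuscleParams, MuscleSet
from stsnorm.normalization import (
    StaticOptimization,
    TorqueNormalization,
    evaluate_fit,
    objective_z,
    percent_relative_error,
    simulate_torques,
)

from conftest import toy_problem


# -- objective ---------------------------------------------------------------

def test_objective_z_examples():
    t = np.column_stack([np.sin(np.linspace(0, np.pi, 50)) * a
                         for a in (10.0, 20.0, 30.0, 40.0)])
    assert objective_z(t, t) == 0.0
    # maxima differ by 1 N*m at exactly one joint, minima equal
    shifted = t.copy()
    shifted[:, 2] = np.clip(t[:, 2], None, t[:, 2].max() - 1.0)
    assert objective_z(t, shifted) == pytest.approx(1.0)
    # maxima and minima each differ by (1,1,1,1)
    assert objective_z(t, t - 1.0) == pytest.approx(8.0)
    with pytest.raises(ValidationError):
        objective_z(t, t[:, :3])


# -- simulate_torques --------------------------------------------------------

def test_simulate_torques_limits_and_linearity():
    envelopes, kin, muscles, alpha_true = toy_problem()
    # alpha = 0 -> pure passive torque (zero here: lhat < 1 for the toy)
    tau0 = simulate_torques(envelopes, np.zeros(4), kin, muscles)
    np.testing.assert_allclose(tau0, 0.0, atol=1e-12)
    # doubling one alpha doubles exactly that muscle's active contribution
    a = np.array([0.5, 0.5, 0.5, 0.5])
    b = a.copy()
    b[1] *= 2.0
    d = simulate_torques(envelopes, b, kin, muscles) - simulate_torques(
        envelopes, a, kin, muscles)
    base = simulate_torques(envelopes, np.array([0, 0.5, 0, 0]), kin, muscles)
    np.testing.assert_allclose(d, base - tau0, atol=1e-12)
    assert np.all(d[:, [0, 2, 3]] == 0.0)
    # bound violation raised in strict mode
    with pytest.raises(ValidationError):
        simulate_torques(envelopes, np.full(4, 10.0), kin, muscles)
    with pytest.raises(ValidationError):
        simulate_torques(envelopes, np.full(4, -1.0), kin, muscles)


def test_simulate_torques_closed_loop(noise_free_trial, default_muscles):
    """Generator self-consistency: alpha* reproduces the target torques."""
    trial = noise_free_trial
    tau = simulate_torques(trial.envelopes_true, trial.alpha_true,
                           trial.kinematics_true, default_muscles)
    np.testing.assert_allclose(tau, trial.torques_target, atol=1e-8)


# -- optimizer ---------------------------------------------------------------

def test_fit_identity_optimum():
    """Envelopes already equal to the true activations -> alpha = 1, Z ~ 0."""
    envelopes, kin, muscles, _ = toy_problem()
    target = simulate_torques(envelopes, np.ones(4), kin, muscles)
    result = TorqueNormalization(envelopes, target, kin, muscles=muscles).fit(seed=0)
    np.testing.assert_allclose(result.alpha, 1.0, atol=1e-3)
    assert result.z < 1e-10


def test_fit_is_deterministic():
    envelopes, kin, muscles, alpha_true = toy_problem()
    target = simulate_torques(envelopes, alpha_true, kin, muscles)
    model = TorqueNormalization(envelopes, target, kin, muscles=muscles)
    r1, r2 = model.fit(seed=3), model.fit(seed=3)
    np.testing.assert_array_equal(r1.alpha, r2.alpha)
    assert r1.z == r2.z


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_correlation_and_timing_invariance(seed):
    """For any positive scaling, r(m, e) = 1 and relative-threshold crossing
    times are preserved (pure scaling cannot shift on/off timing)."""
    rng = np.random.default_rng(seed)
    u = np.linspace(0, 1, 101)
    e = np.abs(rng.uniform(0.2, 1.0) * np.exp(-0.5 * ((u - rng.uniform(0.2, 0.8)) / 0.1) ** 2)
               + 0.01 * rng.random(101))
    alpha = rng.uniform(0.05, 1.0 / e.max())
    m = alpha * e
    assert np.corrcoef(m, e)[0, 1] == pytest.approx(1.0, abs=1e-12)
    for frac in (0.1, 0.5, 0.9):
        np.testing.assert_array_equal(m >= frac * m.max(), e >= frac * e.max())


def test_fit_respects_activation_bound():
    """Peaky envelopes with large targets: activation stays within [0, 1]."""
    envelopes, kin, muscles, _ = toy_problem()
    target = simulate_torques(envelopes, np.ones(4), kin, muscles) * 50.0
    result = TorqueNormalization(envelopes, target, kin, muscles=muscles).fit(seed=0)
    assert result.activation.max() <= 1.0 + 1e-9
    assert result.z > 0                     # honest residual, not hidden


def test_fit_degenerate_inputs():
    envelopes, kin, muscles, _ = toy_problem()
    target = np.zeros((len(kin), 4))
    with pytest.raises(DegenerateInputError):
        TorqueNormalization(np.zeros_like(envelopes), target, kin, muscles=muscles)
    with pytest.raises(ValidationError):
        TorqueNormalization(envelopes, np.full((len(kin), 4), np.nan), kin,
                            muscles=muscles)


def test_result_summary_and_dict(noise_free_trial, default_muscles):
    trial = noise_free_trial
    model = TorqueNormalization(trial.envelopes_true, trial.torques_target,
                                trial.kinematics_true, muscles=default_muscles)
    result = model.fit(seed=0)
    text = result.summary()
    assert "objective Z" in text and "alpha" in text and "%RE" in text
    d = result.to_dict()
    assert set(d["alpha"]) == set(s.MUSCLES)
    assert all(abs(v - 1.0) < 1e-9 for v in d["pearson_r"].values())


# -- static-optimization baseline -------------------------------------------

def test_so_single_muscle_algebraic():
    """One muscle, one joint, no passive: m = T / (r Fmax f_fl f_fv)."""
    n = 21
    muscles = MuscleSet([MuscleParams(name="X", fmax=1000.0, l_opt=0.1,
                                      v_max=0.5,
                                      moment_arms=np.array([0.05, 0, 0, 0]))])
    theta = np.full((n, 4), 0.2)            # lhat = 0.9, no passive force
    kin = s.KinematicsSeries(time=np.linspace(0, 1, n), theta=theta,
                             omega=np.zeros((n, 4)), alpha=np.zeros((n, 4)))
    gain = 1000.0 * np.exp(-((0.9 - 1.0) ** 2)) * 0.05
    m_expected = np.linspace(0.0, 0.8, n)
    target = np.zeros((n, 4))
    target[:, 0] = gain * m_expected
    res = StaticOptimization(target, kin, muscles=muscles).fit()
    assert res.feasible.all()
    np.testing.assert_allclose(res.activation[:, 0], m_expected, atol=1e-6)


def test_so_symmetric_muscles_share_load():
    n = 5
    mp = dict(fmax=1000.0, l_opt=0.1, v_max=0.5,
              moment_arms=np.array([0.05, 0, 0, 0]))
    muscles = MuscleSet([MuscleParams(name="A", **mp), MuscleParams(name="B", **mp)])
    theta = np.full((n, 4), 0.2)
    kin = s.KinematicsSeries(time=np.linspace(0, 1, n), theta=theta,
                             omega=np.zeros((n, 4)), alpha=np.zeros((n, 4)))
    target = np.zeros((n, 4))
    target[:, 0] = 20.0
    res = StaticOptimization(target, kin, muscles=muscles).fit()
    np.testing.assert_allclose(res.activation[:, 0], res.activation[:, 1], atol=1e-6)


def test_so_passive_only_torque(default_muscles):
    """Target exactly equal to the passive torque -> zero activation."""
    from stsnorm.muscles import active_torque_basis
    from conftest import analytic_kinematics
    kin = analytic_kinematics(n=31)
    _, P = active_torque_basis(kin, default_muscles)
    res = StaticOptimization(P, kin, muscles=default_muscles).fit()
    assert res.feasible.all()
    np.testing.assert_allclose(res.activation, 0.0, atol=1e-6)


def test_so_infeasible_step_flagged():
    """Unreachable target: least-squares fallback, flagged infeasible."""
    envelopes, kin, muscles, _ = toy_problem()
    target = np.full((len(kin), 4), 1e4)
    res = StaticOptimization(target, kin, muscles=muscles).fit()
    assert not res.feasible.any()
    assert np.all(res.residuals > 0)
    assert "feasible steps       0" in res.summary()


# -- metrics -----------------------------------------------------------------

def test_evaluate_fit_examples():
    u = np.linspace(0, 1, 60)
    ref = np.column_stack([np.sin(np.pi * u), np.cos(np.pi * u) + 1.5])
    same = evaluate_fit(ref, ref, names=("A", "B"))
    assert same["pearson_r"]["A"] == pytest.approx(1.0)
    assert same["rmse_of_peaks"]["B"] == 0.0
    half = evaluate_fit(0.5 * ref, ref, names=("A", "B"))
    assert half["pearson_r"]["A"] == pytest.approx(1.0)
    assert half["rmse_of_peaks"]["A"] == pytest.approx(0.5 * ref[:, 0].max())
    with pytest.warns(RuntimeWarning):
        flat = evaluate_fit(np.zeros_like(ref), ref, names=("A", "B"))
    assert np.isnan(flat["pearson_r"]["A"])
    with pytest.raises(ValidationError):
        evaluate_fit(ref, ref[:-1])


def test_percent_relative_error_example():
    t = np.zeros((10, 4))
    t[:, 0] = np.linspace(0, 100.0, 10)
    sim = t.copy()
    sim[:, 0] *= 1.1
    out = percent_relative_error(sim, t)
    assert out["ankle"] == pytest.approx(10.0)
    assert np.isnan(out["knee"])            # zero reference maximum
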