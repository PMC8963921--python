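"""Hill muscle model: shaping functions, linear torque structure, parameters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stsnorm as s
from stsnorm.errors import ValidationError
from stsnorm.muscles import (
    MuscleParams,
    MuscleSet,
    active_torque_basis,
    muscle_kinematics,
    muscle_tension,
    passive_force,
    simulate_muscle_torques,
    torques_from_tensions,
)

from conftest import analytic_kinematics


# -- shaping functions -------------------------------------------------------

@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(min_value=0.1, max_value=3.0),
       st.floats(min_value=0.1, max_value=3.0))
def test_force_length_unimodal(a, b):
    """f_fl has its unique maximum at l-hat = 1 and decreases away from it."""
    fa, fb = s.force_length(np.array([a]))[0], s.force_length(np.array([b]))[0]
    if abs(a - 1.0) < abs(b - 1.0):
        assert fa >= fb
    assert 0.0 < fa <= 1.0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(min_value=-5.0, max_value=5.0),
       st.floats(min_value=-5.0, max_value=5.0))
def test_force_velocity_strictly_increasing(v1, v2):
    f1, f2 = s.force_velocity(np.array([v1]))[0], s.force_velocity(np.array([v2]))[0]
    if v1 < v2:
        assert f1 < f2
    assert 0.0 < f1 < 2.0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(min_value=0.1, max_value=3.0),
       st.floats(min_value=0.1, max_value=3.0))
def test_passive_force_nondecreasing(a, b):
    fa, fb = passive_force(np.array([a]), 100.0)[0], passive_force(np.array([b]), 100.0)[0]
    if a <= b:
        assert fa <= fb
    assert fa >= 0.0


def test_passive_force_branch_values():
    fmax = 200.0
    lhat = np.array([0.5, 1.0, 1.25, 1.5, 2.0])
    expected = np.array([0.0, fmax * np.exp(-5.0),
                         fmax * np.exp(2.5) / np.exp(5.0), fmax, fmax])
    np.testing.assert_allclose(passive_force(lhat, fmax), expected, rtol=1e-12)
    with pytest.raises(ValidationError):
        passive_force(lhat, 0.0)


# -- torque structure --------------------------------------------------------

def test_torques_from_tensions_examples(default_muscles):
    n = len(default_muscles)
    # all-zero tension -> zero torque
    np.testing.assert_allclose(
        torques_from_tensions(np.zeros((3, n)), default_muscles), 0.0)
    # single muscle, single joint
    one = MuscleSet([MuscleParams(name="X", fmax=100.0, l_opt=0.1, v_max=0.5,
                                  moment_arms=np.array([0.05, 0, 0, 0]))])
    np.testing.assert_allclose(
        torques_from_tensions(np.array([[100.0]]), one), [[5.0, 0, 0, 0]])
    # antagonist pair with equal tension cancels
    pair = MuscleSet([
        MuscleParams(name="AG", fmax=100.0, l_opt=0.1, v_max=0.5,
                     moment_arms=np.array([0.05, 0, 0, 0])),
        MuscleParams(name="AN", fmax=100.0, l_opt=0.1, v_max=0.5,
                     moment_arms=np.array([-0.05, 0, 0, 0])),
    ])
    np.testing.assert_allclose(
        torques_from_tensions(np.array([[80.0, 80.0]]), pair), 0.0, atol=1e-12)


def test_torque_affine_in_activation(default_muscles):
    """tau(m) = P + G m: exactly linear active part on top of the passive."""
    kin = analytic_kinematics(n=51)
    n_m = len(default_muscles)
    rng = np.random.default_rng(11)
    m1 = rng.uniform(0.0, 0.5, size=(51, n_m))
    m2 = rng.uniform(0.0, 0.5, size=(51, n_m))
    tau0 = simulate_muscle_torques(kin, default_muscles, np.zeros((51, n_m)))
    tau1 = simulate_muscle_torques(kin, default_muscles, m1)
    tau2 = simulate_muscle_torques(kin, default_muscles, m2)
    tau12 = simulate_muscle_torques(kin, default_muscles, 0.5 * (m1 + m2))
    np.testing.assert_allclose(tau12 - tau0, 0.5 * ((tau1 - tau0) + (tau2 - tau0)),
                               atol=1e-9)
    # zero activation equals the pure passive torque from the basis
    _, P = active_torque_basis(kin, default_muscles)
    np.testing.assert_allclose(tau0, P, atol=1e-12)


def test_tension_decomposition(default_muscles):
    """Total tension = active + passive; activation 0 leaves passive only."""
    kin = analytic_kinematics(n=51)
    params = default_muscles["SOL"]
    state = muscle_kinematics(kin.theta, kin.omega, params)
    act = np.linspace(0.0, 1.0, 51)
    tension = muscle_tension(params, state, act)
    np.testing.assert_allclose(tension.total, tension.f_ce + tension.f_pe)
    rest = muscle_tension(params, state, np.zeros(51))
    np.testing.assert_allclose(rest.f_ce, 0.0)
    np.testing.assert_allclose(rest.f_pe, tension.f_pe)


def test_muscle_kinematics_linearization():
    params = MuscleParams(name="X", fmax=100.0, l_opt=0.10, v_max=0.5,
                          moment_arms=np.array([0.04, 0, 0, 0]))
    theta = np.zeros((1, 4))
    theta[0, 0] = -0.25                 # lengthens: l = 0.10 + 0.04*0.25
    state = muscle_kinematics(theta, np.zeros((1, 4)), params)
    assert state.lhat[0] == pytest.approx(1.10)
    omega = np.zeros((1, 4))
    omega[0, 0] = 2.0
    state = muscle_kinematics(theta, omega, params)
    assert state.vhat[0] == pytest.approx(0.04 * 2.0 / 0.5)


def test_muscle_kinematics_floor_warning():
    params = MuscleParams(name="X", fmax=100.0, l_opt=0.10, v_max=0.5,
                          moment_arms=np.array([0.05, 0, 0, 0]))
    theta = np.zeros((1, 4))
    theta[0, 0] = 3.0                    # drives length to 0.10 - 0.15 < 0
    with pytest.warns(RuntimeWarning):
        state = muscle_kinematics(theta, np.zeros((1, 4)), params)
    assert state.lhat[0] == 0.1


# -- parameter table ---------------------------------------------------------

def test_default_muscle_set_structure(default_muscles):
    assert default_muscles.names == s.MUSCLES
    assert len(default_muscles) == 11
    for name in ("GAS", "RF", "BFL"):
        arms = default_muscles[name].moment_arms
        assert np.count_nonzero(arms) == 2, f"{name} must be biarticular"
    for params in default_muscles:
        assert params.fmax > 0 and params.l_opt > 0 and params.v_max > 0
        assert np.any(params.moment_arms)


def test_muscle_params_validation():
    with pytest.raises(ValidationError):
        MuscleParams(name="X", fmax=-1.0, l_opt=0.1, v_max=0.5,
                     moment_arms=np.array([0.05, 0, 0, 0]))
    with pytest.raises(ValidationError):
        MuscleParams(name="X", fmax=1.0, l_opt=0.1, v_max=0.5,
                     moment_arms=np.zeros(4))
    with pytest.raises(ValidationError):
        MuscleSet([])
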