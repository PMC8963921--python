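"""Shared fixtures: analytic trajectories, toy problems, cached synthetic trials."""

from __future__ import annotations

import numpy as np
import pytest

from stsnorm import BodyModel, KinematicsSeries, MuscleSet, SynthConfig
from stsnorm.muscles import MuscleParams
from stsnorm.synthetic import gen_trial, minimum_jerk


def analytic_kinematics(n: int = 601, duration: float = 3.0,
                        sit=(0.20, -1.65, 1.55, 0.30),
                        stand=(0.05, -0.05, 0.05, 0.06)) -> KinematicsSeries:
    """Smooth minimum-jerk chain trajectory with closed-form derivatives.

    Default postures keep the lumbar angle above the viscous dead zone so the
    torque series stays continuous (needed by interpolation-based checks).
    """
    t = np.linspace(0.0, duration, n)
    theta = np.empty((n, 4))
    omega = np.empty((n, 4))
    alpha = np.empty((n, 4))
    for j in range(4):
        theta[:, j], omega[:, j], alpha[:, j] = minimum_jerk(
            t, 0.0, duration, sit[j], stand[j])
    return KinematicsSeries(time=t, theta=theta, omega=omega, alpha=alpha)


def toy_problem():
    """One-muscle-per-joint configuration where each scale factor is pinned
    by its joint's torque extrema: static posture (f_fl, f_fv constant),
    normalized length 0.9 (zero passive force), single-joint moment arms.
    """
    n = 101
    u = np.linspace(0.0, 1.0, n)
    envelopes = np.column_stack(
        [0.5 * np.exp(-0.5 * ((u - c) / 0.08) ** 2) for c in (0.2, 0.4, 0.6, 0.8)])
    arms = np.eye(4) * 0.05
    fmax = (1000.0, 2000.0, 1500.0, 800.0)
    muscles = MuscleSet([
        MuscleParams(name=f"M{k}", fmax=f, l_opt=0.1, v_max=0.5, moment_arms=arms[k])
        for k, f in enumerate(fmax)
    ])
    theta = np.full((n, 4), 0.2)       # lhat = (0.1 - 0.05*0.2)/0.1 = 0.9 < 1
    kin = KinematicsSeries(time=3.0 * u, theta=theta,
                           omega=np.zeros((n, 4)), alpha=np.zeros((n, 4)))
    alpha_true = np.array([1.2, 0.6, 1.5, 0.9])
    return envelopes, kin, muscles, alpha_true


@pytest.fixture(scope="session")
def default_muscles() -> MuscleSet:
    return MuscleSet.default()


@pytest.fixture(scope="session")
def default_body() -> BodyModel:
    return BodyModel.from_anthropometry(1.70, 65.0)


@pytest.fixture(scope="session")
def noise_free_trial():
    """Noise-free synthetic trial with full recording (shared, read-only)."""
    return gen_trial(SynthConfig(noise_sd=0.0), include_recording=True)


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise synthetic trial with full recording (shared, read-only)."""
    return gen_trial(SynthConfig(seed=42), trial_seed=123, include_recording=True)
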