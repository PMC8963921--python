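"""Hill-type muscle model for the 11-muscle sit-to-stand musculoskeletal model.

Each muscle i produces tension ``F_i = F_CE + F_PE``: an active contractile
element ``F_CE = Fmax * f_fl(l̂) * f_fv(v̂) * m̂`` scaled by the normalized
activation m̂ in [0, 1], and a passive parallel element engaged above the
optimal length.  The shaping functions are

    f_fl(l̂) = exp(-(l̂ - 1)^2)
    f_fv(v̂) = 1 + tanh(3 v̂)           (v̂ > 0 = shortening, concentric)

and the passive force is piecewise in the normalized length:
0 below l̂ = 1, ``Fmax * e^{10(l̂-1)} / e^5`` on [1, 1.5], and Fmax above.

Muscle kinematics use a constant-moment-arm linearization of the path:
``l(t) = l_ref - Σ_k r_k (θ_k(t) - θ_ref_k)`` so that each muscle's
shortening velocity is ``v = Σ_k r_k θ̇_k``.  Joint torques are the
moment-arm-weighted sums of tensions, ``τ_k = Σ_i r_ki F_i``.  Pennation
and series-elastic tendon dynamics are not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .body import JOINTS
from .dynamics import KinematicsSeries
from .errors import ValidationError

#: canonical muscle order; the first ten carry surface-EMG channels, the
#: iliopsoas (IL) is a deep hip flexor with no measurable surface EMG.
MUSCLES = ("TA", "SOL", "GAS", "RF", "VAS", "BFL", "BFS", "GMAX", "RA", "ES", "IL")
MEASURED_MUSCLES = MUSCLES[:10]

_LHAT_FLOOR = 0.1


@dataclass(frozen=True)
class MuscleParams:
    """Hill parameters and signed constant moment arms for one muscle."""

    name: str
    fmax: float                      # N
    l_opt: float                     # m
    v_max: float                     # m/s
    moment_arms: np.ndarray          # (4,) signed, m; 0 where unattached
    l_ref: float | None = None       # length at the reference posture; default l_opt
    theta_ref: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        object.__setattr__(self, "moment_arms", np.asarray(self.moment_arms, dtype=float))
        object.__setattr__(self, "theta_ref", np.asarray(self.theta_ref, dtype=float))
        if self.fmax <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValidationError(f"{self.name}: fmax, l_opt and v_max must be positive")
        if self.moment_arms.shape != (4,) or not np.any(self.moment_arms):
            raise ValidationError(f"{self.name}: need a (4,) moment-arm vector with a nonzero entry")
        if not np.all(np.isfinite(self.moment_arms)):
            raise ValidationError(f"{self.name}: non-finite moment arm")
        if self.l_ref is None:
            object.__setattr__(self, "l_ref", self.l_opt)


@dataclass(frozen=True)
class MuscleState:
    """Normalized length l̂ and shortening velocity v̂ series for one muscle."""

    lhat: np.ndarray
    vhat: np.ndarray


@dataclass(frozen=True)
class TensionSeries:
    """Active, passive and total tension (N) for one muscle."""

    f_ce: np.ndarray
    f_pe: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.f_ce + self.f_pe


class MuscleSet:
    """Ordered collection of :class:`MuscleParams` with array views."""

    def __init__(self, muscles: list[MuscleParams]):
        if not muscles:
            raise ValidationError("empty muscle set")
        names = [m.name for m in muscles]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate muscle names")
        self.muscles = list(muscles)
        self.names = tuple(names)

    def __len__(self) -> int:
        return len(self.muscles)

    def __getitem__(self, name: str) -> MuscleParams:
        return self.muscles[self.names.index(name)]

    def __iter__(self):
        return iter(self.muscles)

    @property
    def moment_arm_matrix(self) -> np.ndarray:
        """R with shape (4 joints, n muscles)."""
        return np.stack([m.moment_arms for m in self.muscles], axis=1)

    @property
    def fmax(self) -> np.ndarray:
        return np.array([m.fmax for m in self.muscles])

    @classmethod
    def default(cls) -> "MuscleSet":
        with resources.files("stsnorm.defaults").joinpath("muscles.yaml").open() as fh:
            return cls._from_table(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MuscleSet":
        with open(path) as fh:
            return cls._from_table(yaml.safe_load(fh))

    @classmethod
    def _from_table(cls, table: dict) -> "MuscleSet":
        theta_ref = np.asarray(table.get("theta_ref", [0.0] * 4), dtype=float)
        muscles = []
        for name, row in table["muscles"].items():
            arms = np.zeros(4)
            for joint, r in row["moment_arms"].items():
                arms[JOINTS.index(joint)] = r
            muscles.append(MuscleParams(
                name=name, fmax=row["fmax"], l_opt=row["l_opt"], v_max=row["v_max"],
                moment_arms=arms, l_ref=row.get("l_ref"), theta_ref=theta_ref,
            ))
        return cls(muscles)


# ---------------------------------------------------------------------------
# element-wise Hill relations
# ---------------------------------------------------------------------------

def force_length(lhat: np.ndarray) -> np.ndarray:
    """Active force-length factor, Gaussian with maximum 1 at l̂ = 1."""
    lhat = np.asarray(lhat, dtype=float)
    if not np.all(np.isfinite(lhat)):
        raise ValidationError("non-finite normalized length")
    return np.exp(-((lhat - 1.0) ** 2))


def force_velocity(vhat: np.ndarray) -> np.ndarray:
    """Active force-velocity factor, 1 + tanh(3 v̂) in (0, 2); v̂ > 0 = shortening."""
    vhat = np.asarray(vhat, dtype=float)
    if not np.all(np.isfinite(vhat)):
        raise ValidationError("non-finite normalized velocity")
    return 1.0 + np.tanh(3.0 * vhat)


def passive_force(lhat: np.ndarray, fmax: float) -> np.ndarray:
    """Parallel-element passive force: 0 below optimum, exponential rise,
    saturating at Fmax for l̂ > 1.5."""
    if fmax <= 0:
        raise ValidationError("fmax must be positive")
    lhat = np.asarray(lhat, dtype=float)
    mid = fmax * np.exp(10.0 * (lhat - 1.0)) / np.exp(5.0)
    return np.where(lhat < 1.0, 0.0, np.where(lhat > 1.5, fmax, mid))


def active_force(fmax: float, f_fl: np.ndarray, f_fv: np.ndarray,
                 activation: np.ndarray) -> np.ndarray:
    """Contractile-element force ``Fmax * f_fl * f_fv * m̂`` with m̂ in [0, 1]."""
    activation = np.asarray(activation, dtype=float)
    if np.any(activation < -1e-12) or np.any(activation > 1.0 + 1e-9):
        raise ValidationError("activation must lie in [0, 1]")
    return fmax * f_fl * f_fv * np.clip(activation, 0.0, 1.0)


# ---------------------------------------------------------------------------
# kinematics-dependent quantities
# ---------------------------------------------------------------------------

def muscle_kinematics(theta: np.ndarray, omega: np.ndarray,
                      params: MuscleParams) -> MuscleState:
    """Normalized length/velocity series from joint kinematics.

    Linearized path: ``l = l_ref - Σ_k r_k (θ_k - θ_ref_k)``; the shortening
    velocity is ``v = Σ_k r_k θ̇_k`` and both are normalized by ``l_opt``
    and ``v_max``.  l̂ is floored at 0.1 (with a warning) should the
    linearization drive it non-physical.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    r = params.moment_arms
    length = params.l_ref - (theta - params.theta_ref[None, :]) @ r
    lhat = length / params.l_opt
    if np.any(lhat <= _LHAT_FLOOR):
        warnings.warn(f"{params.name}: normalized length clamped at {_LHAT_FLOOR}",
                      RuntimeWarning, stacklevel=2)
        lhat = np.maximum(lhat, _LHAT_FLOOR)
    vhat = (omega @ r) / params.v_max
    return MuscleState(lhat=lhat, vhat=vhat)


def muscle_tension(params: MuscleParams, state: MuscleState,
                   activation: np.ndarray) -> TensionSeries:
    """Active + passive tension for one muscle given its state and m̂."""
    f_fl = force_length(state.lhat)
    f_fv = force_velocity(state.vhat)
    f_ce = active_force(params.fmax, f_fl, f_fv, activation)
    f_pe = passive_force(state.lhat, params.fmax)
    return TensionSeries(f_ce=f_ce, f_pe=f_pe)


def torques_from_tensions(tensions: np.ndarray, muscle_set: MuscleSet) -> np.ndarray:
    """Map total muscle tensions (T, n) to joint torques (T, 4): τ_k = Σ_i r_ki F_i."""
    tensions = np.atleast_2d(np.asarray(tensions, dtype=float))
    if tensions.shape[1] != len(muscle_set):
        raise ValidationError("tension columns must match the muscle set")
    return tensions @ muscle_set.moment_arm_matrix.T


def active_torque_basis(kin: KinematicsSeries, muscle_set: MuscleSet):
    """Linear structure of the muscle torques in the activation vector.

    Returns ``(G, P)`` where ``G[t, k, i] = r_ki Fmax_i f_fl f_fv`` is the
    active torque produced per unit activation of muscle i at joint k and
    time t, and ``P[t, k]`` is the passive torque.  At fixed kinematics the
    total simulated torque is affine in activation: ``τ = P + G m̂``.
    """
    n_t = len(kin)
    n_m = len(muscle_set)
    R = muscle_set.moment_arm_matrix           # (4, n)
    gain = np.empty((n_t, n_m))
    P = np.zeros((n_t, 4))
    for i, params in enumerate(muscle_set):
        state = muscle_kinematics(kin.theta, kin.omega, params)
        gain[:, i] = params.fmax * force_length(state.lhat) * force_velocity(state.vhat)
        P += np.outer(passive_force(state.lhat, params.fmax), R[:, i])
    G = gain[:, None, :] * R[None, :, :]
    return G, P


def simulate_muscle_torques(kin: KinematicsSeries, muscle_set: MuscleSet,
                            activation: np.ndarray) -> np.ndarray:
    """Joint torques (T, 4) from activation series (T, n) on given kinematics."""
    activation = np.asarray(activation, dtype=float)
    if activation.shape != (len(kin), len(muscle_set)):
        raise ValidationError("activation must have shape (n_samples, n_muscles)")
    G, P = active_torque_basis(kin, muscle_set)
    return P + np.einsum("tki,ti->tk", G, np.clip(activation, 0.0, 1.0))
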