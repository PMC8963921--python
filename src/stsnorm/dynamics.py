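"""Planar four-link rigid-body dynamics: inverse and forward.

Joint torques during sit-to-stand satisfy the chain equation of motion

    I(Θ, Θ̇) Θ̈ + H(Θ, Θ̇) + g(Θ) + Ψ(Θ, Θ̇) = T_jnt + Φ(Θ),

where Ψ is the joint viscous resistance and Φ the generalized force of the
seat (hip) reaction.  Given measured kinematics and reaction forces, T_jnt
is the only unknown (inverse dynamics); given T_jnt, the same terms define
the forward initial-value problem used for consistency checks.

Angle convention
----------------
Joint angles are chain-relative: ``theta[k]`` rotates segment ``k`` relative
to segment ``k-1`` (segment 0 relative to the vertical ground axis),
counterclockwise positive with the subject facing +x.  Increasing angle is
dorsiflexion at the ankle, extension at the knee, and flexion at the hip and
lumbar; muscle moment-arm signs in the default parameter table encode the
same convention.  The absolute inclination of segment ``k`` from vertical is
``phi[k] = theta[0] + ... + theta[k]`` and a segment of length L spans the
vector ``L * (sin phi, cos phi)``.

The equations are assembled in closed Lagrangian form over the absolute
angles (mass matrix ``A_jk cos(phi_j - phi_k) + I_j δ_jk``) and mapped to
relative coordinates, which keeps every term explicit and vectorizes over
time.  Foot-plate reactions act at ground-fixed points under the grounded
ankle root and therefore produce no generalized torque; only the hip (seat)
reaction, applied on the moving pelvis segment, enters Φ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .body import GRAVITY, JOINTS, LUMBAR_DEAD_ZONE, BodyModel
from .errors import RuntimeComputationError, ValidationError

#: index of the segment carrying the seat contact point (pelvis)
_PELVIS = 2


@dataclass(frozen=True)
class KinematicsSeries:
    """Joint angles Θ with first and second time derivatives, shape (T, 4)."""

    time: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for arr, name in ((self.theta, "theta"), (self.omega, "omega"), (self.alpha, "alpha")):
            if arr.shape != (n, 4):
                raise ValidationError(f"{name} must have shape (n_samples, 4)")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class ExternalForces:
    """Seat (hip) reaction applied on the pelvis; foot reactions carried as data.

    ``hip`` is an (T, 2) array of (horizontal, vertical) force in N, zero
    from seat-off onward.  ``feet`` is an optional (T, 2) total foot-plate
    reaction; it is preserved for reporting but exerts no generalized torque
    on the grounded chain (see module docstring).
    """

    hip: np.ndarray
    feet: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hip.ndim != 2 or self.hip.shape[1] != 2:
            raise ValidationError("hip force must have shape (n_samples, 2)")

    @classmethod
    def none(cls, n: int) -> "ExternalForces":
        return cls(hip=np.zeros((n, 2)))


def differentiate_kinematics(
    theta: np.ndarray,
    rate: float,
    smoothing_window: int = 0,
    time: np.ndarray | None = None,
) -> KinematicsSeries:
    """Numerically differentiate joint angles (central differences).

    An optional centered moving average of ``smoothing_window`` samples is
    applied before differencing.  Endpoints use one-sided differences.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    if theta.shape[0] < 5:
        raise ValidationError("need at least 5 samples to differentiate")
    if theta.shape[1] != 4:
        raise ValidationError("expected 4 joint-angle series")
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.pad(theta, ((pad, pad), (0, 0)), mode="edge")
        theta = np.column_stack([
            np.convolve(padded[:, j], kernel, mode="valid")[: theta.shape[0]]
            for j in range(4)
        ])
    dt = 1.0 / rate
    omega = np.gradient(theta, dt, axis=0)
    alpha = np.gradient(omega, dt, axis=0)
    if time is None:
        time = np.arange(theta.shape[0]) * dt
    return KinematicsSeries(time=time, theta=theta, omega=omega, alpha=alpha)


def viscous_resistance(theta: np.ndarray, omega: np.ndarray, body: BodyModel) -> np.ndarray:
    """Joint viscous resistance Ψ, shape (T, 4).

    Ankle/knee/hip: ``d_k * θ̇_k``.  Lumbar: angle-proportional with
    separate extension/flexion coefficients and a dead zone for
    ``|θ_4| <= 0.0314`` rad where Ψ_4 = 0 (the piecewise form is taken as
    printed; no continuity correction is applied at the branch boundaries).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    psi = np.zeros_like(theta)
    d = np.asarray(body.viscous)
    psi[:, :3] = omega[:, :3] * d[None, :]
    th4 = theta[:, 3]
    psi[:, 3] = np.where(
        th4 > LUMBAR_DEAD_ZONE, body.lumbar_extension * th4,
        np.where(th4 < -LUMBAR_DEAD_ZONE, body.lumbar_flexion * th4, 0.0),
    )
    return psi


# ---------------------------------------------------------------------------
# chain geometry helpers
# ---------------------------------------------------------------------------

def _chain_coefficients(body: BodyModel):
    """Constant matrices of the absolute-angle Lagrangian.

    ``r[i, j]`` is the lever of absolute angle j in the position of COM i
    (segment length below the COM's segment, COM offset on it, 0 above).
    Returns (A, b, I) with ``A = r^T diag(m) r`` (coupling inertia),
    ``b_j = sum_i m_i r_ij`` (gravity lever), ``I`` rotational inertias.
    """
    L, m, c, inertia = body.lengths, body.masses, body.coms, body.inertias
    r = np.zeros((4, 4))
    for i in range(4):
        r[i, :i] = L[:i]
        r[i, i] = c[i]
    A = r.T @ np.diag(m) @ r
    b = m @ r
    return A, b, inertia


def _lower_ones() -> np.ndarray:
    return np.tril(np.ones((4, 4)))


def _hip_levers(body: BodyModel) -> np.ndarray:
    """Lever of each absolute angle in the seat contact-point position."""
    L = body.lengths
    rho = body.hip_contact_fraction * L[_PELVIS]
    return np.array([L[0], L[1], rho, 0.0])


def _generalized_terms(kin: KinematicsSeries, body: BodyModel):
    """Per-sample inertial+velocity+gravity generalized force in absolute coords.

    Returns ``Q`` with shape (T, 4): ``Q_j = Σ_k M_jk φ̈_k +
    Σ_k A_jk sin(φ_j-φ_k) φ̇_k² - g b_j sin φ_j``.
    """
    A, b, inertia = _chain_coefficients(body)
    Lmat = _lower_ones()
    phi = kin.theta @ Lmat.T
    dphi = kin.omega @ Lmat.T
    ddphi = kin.alpha @ Lmat.T
    dphase = phi[:, :, None] - phi[:, None, :]          # (T, j, k)
    M = A[None, :, :] * np.cos(dphase)
    M += np.diag(inertia)[None, :, :]
    Q = np.einsum("tjk,tk->tj", M, ddphi)
    Q += np.einsum("jk,tjk,tk->tj", A, np.sin(dphase), dphi ** 2)
    Q += -GRAVITY * b[None, :] * np.sin(phi)
    return Q, M, phi


def _hip_generalized(phi: np.ndarray, hip: np.ndarray, body: BodyModel) -> np.ndarray:
    """Generalized force of the seat reaction in absolute coords, (T, 4)."""
    lev = _hip_levers(body)
    # ∂p/∂φ_j = lever_j * (cos φ_j, -sin φ_j)
    return lev[None, :] * (hip[:, 0:1] * np.cos(phi) - hip[:, 1:2] * np.sin(phi))


def inverse_dynamics(
    kin: KinematicsSeries,
    forces: ExternalForces,
    body: BodyModel,
) -> np.ndarray:
    """Joint torques T_jnt (T, 4: ankle, knee, hip, lumbar) from kinematics.

    Solves the equation of motion for the torque term:
    ``T = [inertial + velocity + gravity]_rel + Ψ - Φ_rel``.
    """
    if len(forces.hip) != len(kin):
        raise ValidationError("kinematics and forces must share the time base")
    Q, _, phi = _generalized_terms(kin, body)
    Q_ext = _hip_generalized(phi, forces.hip, body)
    # relative-coordinate generalized force: reverse cumulative sum over joints
    torques = np.cumsum((Q - Q_ext)[:, ::-1], axis=1)[:, ::-1]
    torques += viscous_resistance(kin.theta, kin.omega, body)
    if not np.all(np.isfinite(torques)):
        raise RuntimeComputationError("inverse dynamics produced non-finite torques")
    return torques


def forward_dynamics(
    torques: np.ndarray,
    time: np.ndarray,
    forces: ExternalForces,
    body: BodyModel,
    theta0: np.ndarray,
    omega0: np.ndarray,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-11,
):
    """Integrate the chain forward under prescribed joint torques.

    ``torques`` and ``forces`` are sampled on ``time`` and interpolated with
    cubic splines.  Returns ``(theta(t_eval), omega(t_eval))``.  Used as the
    dynamics-residual check against :func:`inverse_dynamics`.
    """
    tau_s = CubicSpline(time, torques, axis=0)
    hip_s = CubicSpline(time, forces.hip, axis=0)
    A, b, inertia = _chain_coefficients(body)
    Lmat = _lower_ones()
    lev = _hip_levers(body)

    def rhs(t, y):
        theta, omega = y[:4], y[4:]
        phi = Lmat @ theta
        dphi = Lmat @ omega
        dphase = phi[:, None] - phi[None, :]
        M = A * np.cos(dphase) + np.diag(inertia)
        vel = (A * np.sin(dphase)) @ (dphi ** 2)
        grav = -GRAVITY * b * np.sin(phi)
        hip = hip_s(t)
        q_ext = lev * (hip[0] * np.cos(phi) - hip[1] * np.sin(phi))
        psi = viscous_resistance(theta[None, :], omega[None, :], body)[0]
        rhs_rel = tau_s(t) + Lmat.T @ q_ext - psi - Lmat.T @ (vel + grav)
        M_rel = Lmat.T @ M @ Lmat
        acc = np.linalg.solve(M_rel, rhs_rel)
        return np.concatenate([omega, acc])

    if t_eval is None:
        t_eval = time
    sol = solve_ivp(rhs, (time[0], time[-1]), np.concatenate([theta0, omega0]),
                    t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeComputationError(f"forward integration failed: {sol.message}")
    return sol.y[:4].T, sol.y[4:].T


def mechanical_energy(kin: KinematicsSeries, body: BodyModel) -> np.ndarray:
    """Total kinetic + potential energy of the chain per sample (J)."""
    A, b, inertia = _chain_coefficients(body)
    Lmat = _lower_ones()
    phi = kin.theta @ Lmat.T
    dphi = kin.omega @ Lmat.T
    dphase = phi[:, :, None] - phi[:, None, :]
    M = A[None, :, :] * np.cos(dphase) + np.diag(inertia)[None, :, :]
    ke = 0.5 * np.einsum("tj,tjk,tk->t", dphi, M, dphi)
    pe = GRAVITY * (np.cos(phi) @ b)
    return ke + pe


def joint_positions(theta: np.ndarray, body: BodyModel) -> np.ndarray:
    """Cartesian joint positions (T, 5, 2): ankle, knee, hip, lumbar, HAT tip."""
    theta = np.atleast_2d(theta)
    phi = theta @ _lower_ones().T
    L = body.lengths
    seg = np.stack([L * np.sin(phi), L * np.cos(phi)], axis=-1)  # (T, 4, 2)
    pts = np.zeros((theta.shape[0], 5, 2))
    pts[:, 1:, :] = np.cumsum(seg, axis=1)
    return pts
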