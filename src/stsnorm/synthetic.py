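"""Self-consistent synthetic sit-to-stand trials with known ground truth.

Every downstream stage is testable without measured data: the generator
emits raw-format trial recordings together with the quantities the pipeline
is supposed to recover (true activations m̂*, scale factors α*, synergy
matrices W*/C*, target torques, seat-off time).

Construction
------------
* Joint trajectories are minimum-jerk (quintic) interpolations from a
  sitting to a standing posture, so Θ̇ and Θ̈ are closed-form; the lumbar
  joint additionally performs a flexion-then-extension excursion peaking
  before seat-off (two glued quintics, C² everywhere).
* Muscle activations follow the four-synergy model: M* = W* C* with
  Gaussian-bump temporal patterns whose phase order (body flexion, hip
  raise, body extension, posture control) and spatial dominance (RA, TA,
  VAS/ES, SOL) mirror healthy sit-to-stand coordination.
* EMG envelopes are exact positive rescalings e_i = m̂*_i / α*_i, optionally
  degraded with multiplicative noise (scale-invariant, since the pipeline's
  estimand is a scale factor).
* Reaction forces satisfy quasi-static vertical balance: the seat (hip)
  force unloads along a quintic ramp crossing the 10 N seat-off threshold
  exactly at the configured time, feet carrying the remainder of body
  weight.  Full dynamic consistency is deliberately not imposed here; the
  dedicated forward-inverse dynamics property test bypasses this generator.
* Target torques T* are the forward Hill-model torques at m̂* on the
  generated kinematics, making the normalization problem exactly
  self-consistent (Z = 0 at α = α*).

All randomness flows from seeded ``numpy`` generators; a fixed configuration
reproduces byte-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .body import GRAVITY, JOINTS, BodyModel
from .dynamics import ExternalForces, KinematicsSeries
from .errors import ValidationError
from .muscles import MEASURED_MUSCLES, MUSCLES, MuscleSet, simulate_muscle_torques
from .normalization import default_il_template
from .preprocessing import (
    DEFAULT_PROGRESS_SAMPLES,
    SEAT_OFF_THRESHOLD_N,
    TrialRecording,
    WINDOW_AFTER_S,
    WINDOW_BEFORE_S,
)

# spatial synergy templates W* (10 measured muscles x 4 synergies); column
# dominance: RA (body flexion), TA (hip raise), VAS+ES (body extension),
# SOL (posture control)
DEFAULT_SPATIAL = np.array([
    # S1    S2    S3    S4
    [0.15, 1.00, 0.10, 0.05],   # TA
    [0.05, 0.05, 0.30, 1.00],   # SOL
    [0.05, 0.10, 0.25, 0.60],   # GAS
    [0.10, 0.30, 0.60, 0.10],   # RF
    [0.10, 0.40, 1.00, 0.15],   # VAS
    [0.20, 0.10, 0.40, 0.30],   # BFL
    [0.15, 0.10, 0.35, 0.25],   # BFS
    [0.10, 0.25, 0.70, 0.20],   # GMAX
    [1.00, 0.20, 0.05, 0.05],   # RA
    [0.10, 0.15, 0.90, 0.30],   # ES
])

DEFAULT_CENTERS_PCT = (15.0, 35.0, 60.0, 85.0)
DEFAULT_WIDTHS_PCT = (8.0, 8.0, 10.0, 10.0)
DEFAULT_AMPLITUDES = (0.5, 0.7, 0.8, 0.5)

#: true per-muscle scale factors (10 measured + IL free scale)
DEFAULT_ALPHA_TRUE = (0.9, 1.5, 1.2, 0.8, 1.1, 1.3, 0.7, 1.0, 1.4, 0.6, 0.4)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator (all units SI)."""

    seed: int = 0
    height: float = 1.70
    mass: float = 65.0
    duration: float = 3.0                       # trial window length, s
    recording_duration: float = 6.0
    seat_off_time: float = 2.5
    emg_rate: float = 2000.0
    force_rate: float = 2000.0
    angle_rate: float = 100.0
    sit_posture: tuple = (0.20, -1.65, 1.55, 0.05)
    stand_posture: tuple = (0.05, -0.05, 0.05, 0.0)
    lumbar_flexion_amp: float = 0.25            # rad, pre-seat-off excursion
    lumbar_flexion_peak_frac: float = 0.25      # of the motion window
    spatial: np.ndarray = field(default_factory=lambda: DEFAULT_SPATIAL.copy())
    centers_pct: tuple = DEFAULT_CENTERS_PCT
    widths_pct: tuple = DEFAULT_WIDTHS_PCT
    amplitudes: tuple = DEFAULT_AMPLITUDES
    alpha_true: tuple = DEFAULT_ALPHA_TRUE
    noise_sd: float = 0.05                      # multiplicative EMG noise
    seat_load_fraction: float = 0.6             # of body weight while seated
    unload_ramp_s: float = 1.0
    progress_samples: int = DEFAULT_PROGRESS_SAMPLES
    n_days: int = 2
    trials_per_day: int = 10
    growth: tuple = (1.0, 1.0, 1.0, 1.0)        # per-synergy per-day factor

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("trial duration must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if any(a <= 0 for a in self.alpha_true):
            raise ValidationError("true scale factors must be positive")
        if np.any(np.asarray(self.spatial) < 0):
            raise ValidationError("spatial templates must be non-negative")

    @property
    def motion_start(self) -> float:
        return self.seat_off_time - WINDOW_BEFORE_S

    @property
    def motion_end(self) -> float:
        return self.seat_off_time + WINDOW_AFTER_S

    def body_model(self) -> BodyModel:
        return BodyModel.from_anthropometry(self.height, self.mass)


@dataclass
class SynthTrial:
    """One generated trial: raw streams plus ground truth."""

    recording: TrialRecording | None
    activation_true: np.ndarray         # (progress, 11)
    envelopes_true: np.ndarray          # (progress, 10) = m̂*/α*
    alpha_true: np.ndarray              # (11,)
    W_true: np.ndarray
    C_true: np.ndarray
    kinematics_true: KinematicsSeries   # on the progress grid over the window
    forces_true: ExternalForces
    torques_target: np.ndarray          # (progress, 4) forward Hill torques at m̂*
    seat_off_time: float
    config: SynthConfig


# ---------------------------------------------------------------------------
# closed-form trajectory primitives
# ---------------------------------------------------------------------------

def minimum_jerk(t, t0: float, t1: float, q0: float, q1: float):
    """Quintic minimum-jerk interpolation with analytic derivatives.

    Returns ``(q, qd, qdd)`` evaluated at ``t`` (scalar or array); constant
    (zero-derivative) outside ``[t0, t1]``.
    """
    t = np.asarray(t, dtype=float)
    if t1 <= t0:
        raise ValidationError("minimum-jerk interval must have positive duration")
    T = t1 - t0
    u = np.clip((t - t0) / T, 0.0, 1.0)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    sd = (30 * u**2 - 60 * u**3 + 30 * u**4) / T
    sdd = (60 * u - 180 * u**2 + 120 * u**3) / T**2
    dq = q1 - q0
    return q0 + dq * s, dq * sd, dq * sdd


def _lumbar_bump(t, t0: float, t_peak: float, t1: float, amp: float):
    """Flexion excursion: quintic rise 0→amp on [t0, t_peak], fall amp→0 on
    [t_peak, t1].  C² everywhere, zero value/derivatives at both ends."""
    up = minimum_jerk(t, t0, t_peak, 0.0, amp)
    down = minimum_jerk(t, t_peak, t1, amp, 0.0)
    t = np.asarray(t, dtype=float)
    mask = t < t_peak
    return tuple(np.where(mask, u, d) for u, d in zip(up, down))


def gen_kinematics(cfg: SynthConfig, time: np.ndarray) -> KinematicsSeries:
    """Analytic joint kinematics at absolute times ``time`` (s)."""
    time = np.asarray(time, dtype=float)
    t0, t1 = cfg.motion_start, cfg.motion_end
    theta = np.empty((len(time), 4))
    omega = np.empty_like(theta)
    alpha = np.empty_like(theta)
    for j in range(4):
        q, qd, qdd = minimum_jerk(time, t0, t1, cfg.sit_posture[j], cfg.stand_posture[j])
        if j == 3 and cfg.lumbar_flexion_amp != 0:
            t_peak = t0 + cfg.lumbar_flexion_peak_frac * (t1 - t0)
            b, bd, bdd = _lumbar_bump(time, t0, t_peak, t1, cfg.lumbar_flexion_amp)
            q, qd, qdd = q + b, qd + bd, qdd + bdd
        theta[:, j], omega[:, j], alpha[:, j] = q, qd, qdd
    return KinematicsSeries(time=time, theta=theta, omega=omega, alpha=alpha)


# ---------------------------------------------------------------------------
# activations and synergies
# ---------------------------------------------------------------------------

def gen_activations(cfg: SynthConfig, growth: np.ndarray | None = None):
    """Ground-truth synergy decomposition on the progress grid.

    Returns ``(M, W, C)`` with M = clip(W C, 0, 1), shape (10, progress).
    ``growth`` optionally scales each synergy's temporal amplitude
    (longitudinal amplitude change).
    """
    u = np.linspace(0.0, 100.0, cfg.progress_samples)
    amps = np.asarray(cfg.amplitudes, dtype=float)
    if growth is not None:
        amps = amps * np.asarray(growth, dtype=float)
    C = np.stack([
        a * np.exp(-0.5 * ((u - c) / w) ** 2)
        for a, c, w in zip(amps, cfg.centers_pct, cfg.widths_pct)
    ])
    W = np.asarray(cfg.spatial, dtype=float)
    M = np.clip(W @ C, 0.0, 1.0)
    return M, W, C


def gen_activation_matrix(cfg: SynthConfig, seed: int,
                          growth: np.ndarray | None = None) -> np.ndarray:
    """Noisy activation matrix (10 x progress): M* with multiplicative noise."""
    M, _, _ = gen_activations(cfg, growth)
    rng = np.random.default_rng(seed)
    noisy = M * (1.0 + cfg.noise_sd * rng.standard_normal(M.shape))
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _hip_force_profile(cfg: SynthConfig, time: np.ndarray) -> np.ndarray:
    """Seat vertical force: quintic unloading ramp crossing the 10 N
    threshold exactly at the configured seat-off time."""
    f0 = cfg.seat_load_fraction * cfg.mass * GRAVITY
    if f0 <= SEAT_OFF_THRESHOLD_N:
        raise ValidationError("seated load must exceed the seat-off threshold")
    target = 1.0 - SEAT_OFF_THRESHOLD_N / f0

    def ramp(u):
        return 10 * u**3 - 15 * u**4 + 6 * u**5

    u_cross = brentq(lambda u: ramp(u) - target, 0.0, 1.0, xtol=1e-14)
    a = cfg.seat_off_time - u_cross * cfg.unload_ramp_s
    if a < 0:
        raise ValidationError("unloading ramp starts before the recording")
    q, _, _ = minimum_jerk(time, a, a + cfg.unload_ramp_s, 1.0, 0.0)
    return f0 * q


def gen_forces(cfg: SynthConfig, time: np.ndarray) -> dict[str, np.ndarray]:
    """Quasi-statically balanced reaction forces at absolute times."""
    hip = _hip_force_profile(cfg, time)
    feet = cfg.mass * GRAVITY - hip
    if np.any(feet < 0):
        raise ValidationError("negative foot load: infeasible force profile")
    return {
        "hip": hip,
        "hip_x": np.zeros_like(hip),
        "lfoot": feet / 2.0,
        "rfoot": feet / 2.0,
    }


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def gen_trial(cfg: SynthConfig, trial_seed: int | None = None,
              growth: np.ndarray | None = None,
              muscles: MuscleSet | None = None,
              include_recording: bool = True) -> SynthTrial:
    """Generate one fully self-consistent trial.

    ``trial_seed`` (default ``cfg.seed``) drives the EMG noise; with
    ``noise_sd = 0`` the emitted envelopes equal m̂*/α* exactly.
    """
    if trial_seed is None:
        trial_seed = cfg.seed
    muscles = muscles if muscles is not None else MuscleSet.default()
    rng = np.random.default_rng(trial_seed)

    # ground truth on the progress grid over the trial window
    M, W, C = gen_activations(cfg, growth)
    alpha = np.asarray(cfg.alpha_true, dtype=float)
    il = alpha[10] * default_il_template(cfg.progress_samples)
    activation = np.column_stack([M.T, il])                     # (progress, 11)
    envelopes = M.T / alpha[None, :10]

    t_prog = cfg.motion_start + (cfg.duration *
                                 np.linspace(0.0, 1.0, cfg.progress_samples))
    kin = gen_kinematics(cfg, t_prog)
    torques = simulate_muscle_torques(kin, muscles, activation)
    forces_prog = gen_forces(cfg, t_prog)
    hip_after_seatoff = t_prog >= cfg.seat_off_time
    hip_y = np.where(hip_after_seatoff, 0.0, forces_prog["hip"])
    ext = ExternalForces(hip=np.column_stack([forces_prog["hip_x"], hip_y]),
                         feet=np.column_stack([np.zeros_like(hip_y),
                                               forces_prog["lfoot"] + forces_prog["rfoot"]]))

    recording = None
    if include_recording:
        recording = _build_recording(cfg, envelopes, t_prog, rng)

    return SynthTrial(
        recording=recording, activation_true=activation,
        envelopes_true=envelopes, alpha_true=alpha, W_true=W, C_true=C,
        kinematics_true=kin, forces_true=ext, torques_target=torques,
        seat_off_time=cfg.seat_off_time, config=cfg,
    )


def _build_recording(cfg: SynthConfig, envelopes: np.ndarray,
                     t_prog: np.ndarray, rng: np.random.Generator) -> TrialRecording:
    n_emg = int(round(cfg.recording_duration * cfg.emg_rate)) + 1
    t_emg = np.arange(n_emg) / cfg.emg_rate
    emg = {}
    for j, name in enumerate(MEASURED_MUSCLES):
        base = np.interp(t_emg, t_prog, envelopes[:, j])
        if cfg.noise_sd > 0:
            base = base * (1.0 + cfg.noise_sd * rng.standard_normal(n_emg))
        emg[name] = np.clip(base, 0.0, None)

    n_frc = int(round(cfg.recording_duration * cfg.force_rate)) + 1
    t_frc = np.arange(n_frc) / cfg.force_rate
    forces = gen_forces(cfg, t_frc)

    n_ang = int(round(cfg.recording_duration * cfg.angle_rate)) + 1
    t_ang = np.arange(n_ang) / cfg.angle_rate
    kin_full = gen_kinematics(cfg, t_ang)
    angles = {j: kin_full.theta[:, k] for k, j in enumerate(JOINTS)}

    return TrialRecording(
        emg=emg, forces=forces, angles=angles,
        rates={"emg": cfg.emg_rate, "force": cfg.force_rate, "angles": cfg.angle_rate},
        subject_id="synthetic", session_day=0, emg_domain="envelope",
    )


# ---------------------------------------------------------------------------
# longitudinal series
# ---------------------------------------------------------------------------

def gen_longitudinal_series(cfg: SynthConfig, kind: str = "trials"):
    """Per-day trial sets with per-synergy amplitude growth.

    Day d scales each synergy amplitude by ``growth**d`` (growth 1 = null
    series).  ``kind="trials"`` yields full :class:`SynthTrial` objects;
    ``kind="activations"`` yields noisy activation matrices only (the fast
    path for feature statistics).  Trial seeds are derived deterministically
    from ``cfg.seed``, day and trial index.
    """
    if cfg.n_days < 2:
        raise ValidationError("need at least two measurement days")
    if cfg.trials_per_day < 2:
        raise ValidationError("need at least two trials per day")
    growth = np.asarray(cfg.growth, dtype=float)
    days = []
    for d in range(cfg.n_days):
        g = growth ** d
        trials = []
        for t in range(cfg.trials_per_day):
            seed = int(np.random.SeedSequence([cfg.seed, d, t]).generate_state(1)[0] % (2**31))
            if kind == "activations":
                trials.append(gen_activation_matrix(cfg, seed, growth=g))
            elif kind == "trials":
                trials.append(gen_trial(cfg, trial_seed=seed, growth=g))
            else:
                raise ValidationError("kind must be 'trials' or 'activations'")
        days.append(trials)
    return days
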