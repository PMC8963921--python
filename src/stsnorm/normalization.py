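"""Joint-torque-based EMG normalization (the core method) and the
static-optimization baseline.

EMG envelopes cannot be normalized to a maximum voluntary contraction when
the subject cannot produce one (e.g. post-stroke paresis).  The method here
replaces the MVC reference with a mechanical one: each measured envelope
``e_i(t)`` is scaled by a single positive factor ``α_i`` into a normalized
activation ``m̂_i(t) = α_i e_i(t)`` in [0, 1], and the factors are chosen so
that the Hill-model joint torques simulated from ``m̂`` match the
inverse-dynamics torques at their per-joint extrema:

    Z(α) = || T_max - τ_max(α) ||²  +  || T_min - τ_min(α) ||²,

where ``T_max/T_min`` stack the per-joint maxima/minima of the
inverse-dynamics torques over the 3-s trial window and ``τ_max/τ_min`` the
same extrema of the simulated torques.  Pure positive scaling (zero
intercept) enforces a perfect positive correlation (Pearson r = 1) between
``m̂_i`` and ``e_i`` by construction, preserving on/off timing and resting
baselines exactly.

The iliopsoas carries no surface EMG; its activation is parameterized as a
bell-shaped hip-flexion-phase template whose scale is a free bounded
variable, and it is excluded from all accuracy metrics.

:class:`TorqueNormalization` is the model object (data in, ``fit()`` out);
:class:`NormalizationResult` carries estimates, diagnostics and
``summary()``.  :class:`StaticOptimization` implements the conventional
per-time-step minimum-squared-activation baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .body import JOINTS
from .dynamics import KinematicsSeries
from .errors import DegenerateInputError, ValidationError
from .muscles import MEASURED_MUSCLES, MuscleSet, active_torque_basis

_ALPHA_FLOOR = 1e-8


def default_il_template(n_samples: int, center: float = 0.35,
                        width: float = 0.12) -> np.ndarray:
    """Bell-shaped iliopsoas activation template over the motion progress.

    A Gaussian bump centered in the hip-flexion phase (around seat-off),
    peak value 1; the optimizer scales it with a free bounded factor.
    """
    u = np.linspace(0.0, 1.0, n_samples)
    return np.exp(-0.5 * ((u - center) / width) ** 2)


def objective_z(t_jnt: np.ndarray, tau_sim: np.ndarray) -> float:
    """Extrema-matching objective: squared Euclidean distance between the
    4-vectors of per-joint torque maxima plus that of the minima."""
    t_jnt = np.asarray(t_jnt, dtype=float)
    tau_sim = np.asarray(tau_sim, dtype=float)
    if t_jnt.shape != tau_sim.shape:
        raise ValidationError("torque series must share a time base")
    d_max = t_jnt.max(axis=0) - tau_sim.max(axis=0)
    d_min = t_jnt.min(axis=0) - tau_sim.min(axis=0)
    return float(d_max @ d_max + d_min @ d_min)


def simulate_torques(envelopes: np.ndarray, alpha: np.ndarray,
                     kin: KinematicsSeries, muscle_set: MuscleSet,
                     free_templates: np.ndarray | None = None,
                     strict: bool = True) -> np.ndarray:
    """Simulated joint torques (T, 4) at scale factors ``alpha``.

    ``envelopes`` has one column per measured muscle (the first columns of
    the muscle set); remaining muscles use ``free_templates`` columns.
    With ``strict`` the activation bound ``α_i e_i <= 1`` is enforced as an
    error; the optimizer instead keeps α inside bounds.
    """
    profiles = _stack_profiles(envelopes, free_templates, len(muscle_set), len(kin))
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (len(muscle_set),):
        raise ValidationError("alpha must have one entry per muscle")
    if np.any(alpha < 0):
        raise ValidationError("scale factors must be non-negative")
    activation = profiles * alpha[None, :]
    if strict and np.any(activation > 1.0 + 1e-9):
        raise ValidationError("alpha drives activation above 1 (bound violation)")
    G, P = active_torque_basis(kin, muscle_set)
    return P + np.einsum("tki,ti->tk", G, np.clip(activation, 0.0, 1.0))


def _stack_profiles(envelopes, free_templates, n_muscles, n_t) -> np.ndarray:
    envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if envelopes.shape[0] != n_t:
        raise ValidationError("envelope rows must match the kinematics time base")
    if np.any(envelopes < 0):
        raise ValidationError("envelopes must be non-negative")
    n_free = n_muscles - envelopes.shape[1]
    if n_free < 0:
        raise ValidationError("more envelope columns than muscles")
    if n_free == 0:
        return envelopes
    if free_templates is None:
        free_templates = np.column_stack(
            [default_il_template(n_t)] * n_free)
    free_templates = np.atleast_2d(np.asarray(free_templates, dtype=float))
    if free_templates.shape != (n_t, n_free):
        raise ValidationError("free templates must have one column per EMG-less muscle")
    return np.column_stack([envelopes, free_templates])


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    """Fitted scale factors and derived quantities.

    ``alpha`` is ordered like the muscle set (measured muscles first, then
    EMG-less free-template muscles).  ``activation`` is the normalized
    activation matrix m̂ (T, n); ``tau_sim`` the simulated torques (T, 4).
    """

    alpha: np.ndarray
    activation: np.ndarray
    tau_sim: np.ndarray
    z: float
    converged: bool
    muscle_names: tuple[str, ...]
    measured_names: tuple[str, ...]
    target_torques: np.ndarray
    envelopes: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def pearson_r(self) -> dict[str, float]:
        """Per-measured-muscle correlation between m̂ and the input envelope."""
        out = {}
        for j, name in enumerate(self.measured_names):
            e = self.envelopes[:, j]
            m = self.activation[:, j]
            if np.std(e) == 0 or np.std(m) == 0:
                out[name] = float("nan")
            else:
                out[name] = float(np.corrcoef(m, e)[0, 1])
        return out

    @property
    def percent_re(self) -> dict[str, float]:
        """Per-joint percentage relative error of torque maxima."""
        out = {}
        for k, joint in enumerate(JOINTS):
            t_max = self.target_torques[:, k].max()
            s_max = self.tau_sim[:, k].max()
            out[joint] = float("nan") if t_max == 0 else abs(s_max - t_max) / abs(t_max) * 100.0
        return out

    def summary(self) -> str:
        lines = ["Joint-torque-based EMG normalization", "=" * 54,
                 f"objective Z          {self.z:.6g} (N*m)^2",
                 f"converged            {self.converged}",
                 f"starts evaluated     {self.diagnostics.get('n_starts', 'n/a')}",
                 "", f"{'muscle':<8}{'alpha':>12}{'peak m^':>12}{'r':>8}"]
        r = self.pearson_r
        for i, name in enumerate(self.muscle_names):
            peak = self.activation[:, i].max()
            r_txt = f"{r[name]:.4f}" if name in r else "--"
            lines.append(f"{name:<8}{self.alpha[i]:>12.5g}{peak:>12.4f}{r_txt:>8}")
        lines.append("")
        lines.append(f"{'joint':<8}{'T max':>12}{'tau max':>12}{'%RE':>8}")
        pre = self.percent_re
        for k, joint in enumerate(JOINTS):
            lines.append(f"{joint:<8}{self.target_torques[:, k].max():>12.4g}"
                         f"{self.tau_sim[:, k].max():>12.4g}{pre[joint]:>8.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": {n: float(a) for n, a in zip(self.muscle_names, self.alpha)},
            "Z": self.z,
            "converged": self.converged,
            "pearson_r": self.pearson_r,
            "percent_RE": self.percent_re,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, (str, bool))},
        }


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class TorqueNormalization:
    """Model: scale EMG envelopes so simulated torque extrema match targets.

    Parameters
    ----------
    envelopes : (T, n_measured) array
        Non-negative EMG envelopes on the trial time base, one column per
        measured muscle in muscle-set order.
    target_torques : (T, 4) array
        Inverse-dynamics joint torques on the same time base.
    kinematics : KinematicsSeries
        Joint kinematics driving the Hill-model torque basis.
    muscles : MuscleSet, optional
        Defaults to the bundled 11-muscle set.
    free_templates : array, optional
        Activation templates for EMG-less muscles (default: hip-flexion
        bell for the iliopsoas).
    regularization : float
        ε of the tie-breaking term ``ε ||α - 1||²`` added to Z; keeps the
        under-determined problem reproducible without moving the optimum
        appreciably.
    """

    def __init__(self, envelopes: np.ndarray, target_torques: np.ndarray,
                 kinematics: KinematicsSeries, muscles: MuscleSet | None = None,
                 free_templates: np.ndarray | None = None,
                 regularization: float = 1e-6):
        self.muscles = muscles if muscles is not None else MuscleSet.default()
        self.kinematics = kinematics
        self.envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
        self.target_torques = np.asarray(target_torques, dtype=float)
        if self.target_torques.shape != (len(kinematics), 4):
            raise ValidationError("target torques must have shape (n_samples, 4)")
        if not np.all(np.isfinite(self.target_torques)):
            raise ValidationError("non-finite target torques")
        if not np.any(self.envelopes):
            raise DegenerateInputError("all envelopes are zero")
        self.profiles = _stack_profiles(self.envelopes, free_templates,
                                        len(self.muscles), len(kinematics))
        self.n_measured = self.envelopes.shape[1]
        self.regularization = regularization
        self.measured_names = tuple(self.muscles.names[: self.n_measured])
        # precompute the affine torque structure: tau = P + (G * profile) @ alpha
        G, self._passive = active_torque_basis(kinematics, self.muscles)
        self._gain = G * self.profiles[:, None, :]      # (T, 4, n)

    @classmethod
    def from_processed_trial(cls, trial, target_torques, kinematics,
                             muscles: MuscleSet | None = None, **kwargs):
        muscles = muscles if muscles is not None else MuscleSet.default()
        measured = [n for n in muscles.names if n in trial.progress_envelopes]
        env = np.column_stack([trial.progress_envelopes[n] for n in measured])
        return cls(env, target_torques, kinematics, muscles=muscles, **kwargs)

    # -- objective -----------------------------------------------------------
    def _tau(self, alpha: np.ndarray) -> np.ndarray:
        return self._passive + np.einsum("tki,i->tk", self._gain, alpha)

    def _objective(self, alpha: np.ndarray) -> float:
        z = objective_z(self.target_torques, self._tau(alpha))
        reg = self.regularization * float(np.sum((alpha - 1.0) ** 2))
        return z + reg

    def _bounds(self) -> list[tuple[float, float]]:
        peaks = self.profiles.max(axis=0)
        ub = np.where(peaks > 0, 1.0 / np.maximum(peaks, 1e-12), 1.0)
        return [(_ALPHA_FLOOR, float(u)) for u in ub]

    def fit(self, seed: int = 0, n_random_starts: int = 6,
            start_fractions: tuple[float, ...] = (0.1, 0.3, 0.6, 0.9),
            maxiter: int | None = None, xtol: float = 1e-8,
            ftol: float = 1e-10) -> NormalizationResult:
        """Minimize Z over α with a deterministic multi-start local search.

        Starts are a coarse lattice of fixed fractions of the per-muscle
        upper bounds, the unit vector α = 1 (clipped into bounds), and
        ``n_random_starts`` seeded log-uniform draws.  Each start is refined
        with bounded Powell search; the best Z wins, ties broken by the
        smaller ||α||.
        """
        bounds = self._bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = [np.clip(f * hi, lo, hi) for f in start_fractions]
        starts.append(np.clip(np.ones(len(self.muscles)), lo, hi))
        rng = np.random.default_rng(seed)
        for _ in range(n_random_starts):
            u = rng.uniform(size=len(self.muscles))
            starts.append(np.clip(hi * (0.02 ** (1 - u)), lo, hi))

        best = None
        trace = []
        options = {"xtol": xtol, "ftol": ftol}
        if maxiter is not None:
            options["maxiter"] = maxiter
        for x0 in starts:
            res = optimize.minimize(self._objective, x0, method="Powell",
                                    bounds=bounds, options=options)
            trace.append(float(res.fun))
            cand = (float(res.fun), float(np.linalg.norm(res.x)), res)
            if best is None or cand[:2] < best[:2]:
                best = cand
        res = best[2]
        alpha = np.clip(res.x, lo, hi)
        activation = np.clip(self.profiles * alpha[None, :], 0.0, 1.0)
        tau = self._tau(alpha)
        return NormalizationResult(
            alpha=alpha, activation=activation, tau_sim=tau,
            z=objective_z(self.target_torques, tau),
            converged=bool(res.success),
            muscle_names=self.muscles.names,
            measured_names=self.measured_names,
            target_torques=self.target_torques,
            envelopes=self.envelopes,
            diagnostics={"n_starts": len(starts), "start_objectives": trace,
                         "solver": "powell", "regularization": self.regularization,
                         "seed": seed, "message": str(res.message)},
        )


# ---------------------------------------------------------------------------
# static-optimization baseline
# ---------------------------------------------------------------------------

@dataclass
class SOResult:
    """Per-time-step minimum-squared-activation solution."""

    activation: np.ndarray          # (T, n)
    residuals: np.ndarray           # (T,) torque equality residual norm
    feasible: np.ndarray            # (T,) bool
    muscle_names: tuple[str, ...]

    def summary(self) -> str:
        lines = ["Static-optimization baseline (min sum of squared activation)",
                 f"time steps           {len(self.residuals)}",
                 f"feasible steps       {int(self.feasible.sum())}",
                 f"max torque residual  {self.residuals.max():.4g} N*m"]
        return "\n".join(lines)


class StaticOptimization:
    """Conventional baseline: at each time step minimize ``Σ_i m_i²`` subject
    to the simulated joint torques equalling the target torques, 0 ≤ m ≤ 1.

    The active torque is linear in activation at fixed kinematics, so each
    step is a small quadratic program (solved with SLSQP); steps where the
    equality is infeasible fall back to a bounded least-squares residual
    minimum and are flagged.
    """

    def __init__(self, target_torques: np.ndarray, kinematics: KinematicsSeries,
                 muscles: MuscleSet | None = None):
        self.muscles = muscles if muscles is not None else MuscleSet.default()
        self.kinematics = kinematics
        self.target_torques = np.asarray(target_torques, dtype=float)
        if not np.all(np.isfinite(self.target_torques)):
            raise ValidationError("non-finite target torques")
        self._G, self._passive = active_torque_basis(kinematics, self.muscles)

    def fit(self, residual_tol: float = 1e-6) -> SOResult:
        n_t = len(self.kinematics)
        n_m = len(self.muscles)
        activation = np.zeros((n_t, n_m))
        residuals = np.zeros(n_t)
        feasible = np.zeros(n_t, dtype=bool)
        x_prev = np.full(n_m, 0.1)
        for t in range(n_t):
            A = self._G[t]                                 # (4, n)
            b = self.target_torques[t] - self._passive[t]
            res = optimize.minimize(
                lambda m: float(m @ m), x_prev, jac=lambda m: 2.0 * m,
                method="SLSQP", bounds=[(0.0, 1.0)] * n_m,
                constraints=[{"type": "eq", "fun": lambda m, A=A, b=b: A @ m - b,
                              "jac": lambda m, A=A: A}],
                options={"maxiter": 200, "ftol": 1e-12},
            )
            x = np.clip(res.x, 0.0, 1.0)
            r = float(np.linalg.norm(A @ x - b))
            if not res.success or r > residual_tol:
                lsq = optimize.lsq_linear(A, b, bounds=(0.0, 1.0))
                if float(np.linalg.norm(A @ lsq.x - b)) < r:
                    x, r = np.clip(lsq.x, 0.0, 1.0), float(np.linalg.norm(A @ lsq.x - b))
            activation[t] = x
            residuals[t] = r
            feasible[t] = r <= residual_tol
            x_prev = x
        return SOResult(activation=activation, residuals=residuals,
                        feasible=feasible, muscle_names=self.muscles.names)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def evaluate_fit(simulated: np.ndarray, reference: np.ndarray,
                 names: tuple[str, ...] = MEASURED_MUSCLES) -> dict:
    """Conformity metrics between simulated and reference activation series.

    Returns per-muscle Pearson r over the motion progress and the absolute
    error between the two series' peak values (``rmse_of_peaks``).
    Zero-variance series yield NaN correlations with a warning.
    """
    simulated = np.atleast_2d(np.asarray(simulated, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if simulated.shape != reference.shape:
        raise ValidationError("simulated and reference must share shape")
    pearson, peaks = {}, {}
    for j, name in enumerate(names[: simulated.shape[1]]):
        s, r = simulated[:, j], reference[:, j]
        if np.std(s) == 0 or np.std(r) == 0:
            import warnings
            warnings.warn(f"{name}: zero-variance series, r undefined",
                          RuntimeWarning, stacklevel=2)
            pearson[name] = float("nan")
        else:
            pearson[name] = float(stats.pearsonr(s, r)[0])
        peaks[name] = float(abs(s.max() - r.max()))
    return {"pearson_r": pearson, "rmse_of_peaks": peaks}


def percent_relative_error(tau_sim: np.ndarray, t_jnt: np.ndarray) -> dict[str, float]:
    """Per-joint %RE between simulated and reference torque maxima."""
    tau_sim = np.asarray(tau_sim, dtype=float)
    t_jnt = np.asarray(t_jnt, dtype=float)
    out = {}
    for k, joint in enumerate(JOINTS):
        t_max = t_jnt[:, k].max()
        out[joint] = float("nan") if t_max == 0 else float(
            abs(tau_sim[:, k].max() - t_max) / abs(t_max) * 100.0)
    return out
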