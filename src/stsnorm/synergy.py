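"""Muscle-synergy extraction by non-negative matrix factorization and
longitudinal feature statistics.

The activation matrix ``M`` (muscles x progress samples) is factored as
``M ≈ W C`` with a spatial matrix ``W`` (muscles x N, relative activation
levels) and a temporal matrix ``C`` (N x progress, time-varying weighting).
Sit-to-stand is well described by N = 4 synergies, matching the movement
phases: body (lumbar) flexion, hip raise, body extension and posture
control.  Factorization uses Lee-Seung multiplicative updates minimizing
the Frobenius error, restarted from several seeded random initializations;
W columns are rescaled to unit maximum with the inverse absorbed into C.

Reconstruction quality is the global variance accounted for,
``100 (1 - ||M - WC||_F² / ||M||_F²)``; 90 % is the customary adequacy
threshold.  Longitudinal feature distributions (per-trial maxima grouped by
session day) are compared with the Wilcoxon rank-sum test (two sessions) or
the Kruskal-Wallis test (three or more).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .muscles import MEASURED_MUSCLES

DEFAULT_N_SYNERGIES = 4
_EPS = 1e-12

#: synergy phase labels in canonical order
SYNERGY_PHASES = ("body_flexion", "hip_raise", "body_extension", "posture_control")


# ---------------------------------------------------------------------------
# NNMF core
# ---------------------------------------------------------------------------

def _mu_factorize(M: np.ndarray, n: int, rng: np.random.Generator,
                  max_iter: int, tol: float):
    """One Lee-Seung multiplicative-update run; returns (W, C, error_trace)."""
    n_rows, n_cols = M.shape
    scale = np.sqrt(M.mean() / max(n, 1)) + _EPS
    W = rng.uniform(0.1, 1.0, size=(n_rows, n)) * scale
    C = rng.uniform(0.1, 1.0, size=(n, n_cols)) * scale
    errors = []
    prev = None
    for _ in range(max_iter):
        C *= (W.T @ M) / (W.T @ W @ C + _EPS)
        W *= (M @ C.T) / (W @ C @ C.T + _EPS)
        err = float(np.linalg.norm(M - W @ C))
        errors.append(err)
        if prev is not None and prev - err < tol * max(prev, _EPS):
            break
        prev = err
    return W, C, np.array(errors)


def extract_synergies(M: np.ndarray, n_synergies: int, seed: int = 0,
                      restarts: int = 20, max_iter: int = 2000,
                      tol: float = 1e-6):
    """Best-of-restarts NNMF of a non-negative activation matrix.

    Returns ``(W, C, error_trace)`` of the restart with the smallest final
    Frobenius error (ties broken by restart order).  W columns are
    normalized to unit maximum, the scale absorbed into C.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValidationError("M must be a 2-D matrix")
    if np.any(M < 0):
        raise ValidationError("activation matrix must be non-negative")
    if not np.all(np.isfinite(M)):
        raise ValidationError("activation matrix contains non-finite entries")
    if n_synergies > M.shape[0]:
        raise ValidationError("more synergies requested than muscles")
    if n_synergies < 1:
        raise ValidationError("need at least one synergy")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        W, C, errors = _mu_factorize(M, n_synergies, rng, max_iter, tol)
        if best is None or errors[-1] < best[2][-1]:
            best = (W, C, errors)
    W, C, errors = best
    col_max = W.max(axis=0)
    col_max[col_max <= 0] = 1.0
    W = W / col_max[None, :]
    C = C * col_max[:, None]
    return W, C, errors


def reconstruction_quality(M: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Percent variance accounted for by the factorization W C."""
    M = np.asarray(M, dtype=float)
    denom = float(np.linalg.norm(M) ** 2)
    if denom == 0:
        raise DegenerateInputError("reconstruction quality undefined for a zero matrix")
    resid = float(np.linalg.norm(M - np.asarray(W) @ np.asarray(C)) ** 2)
    return 100.0 * (1.0 - resid / denom)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class SynergyResult:
    """Extracted synergy set with quality and extraction provenance."""

    W: np.ndarray                       # (n_muscles, N), columns max-normalized
    C: np.ndarray                       # (N, t_max)
    n_synergies: int
    reconstruction_quality: float       # %
    muscle_labels: tuple[str, ...]
    progress: np.ndarray                # % grid for C columns
    seed: int
    restarts: int
    error_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def features(self) -> dict:
        """Peak level and peak time (% progress, first index on ties) per synergy."""
        peak_level = self.C.max(axis=1)
        idx = self.C.argmax(axis=1)
        peak_time = self.progress[idx]
        return {
            "peak_level": peak_level,
            "peak_time_pct": peak_time,
            "spatial_weights": self.W.copy(),
        }

    def reorder(self, permutation: np.ndarray) -> "SynergyResult":
        p = np.asarray(permutation)
        return SynergyResult(
            W=self.W[:, p], C=self.C[p, :], n_synergies=self.n_synergies,
            reconstruction_quality=self.reconstruction_quality,
            muscle_labels=self.muscle_labels, progress=self.progress,
            seed=self.seed, restarts=self.restarts, error_trace=self.error_trace,
        )

    def summary(self) -> str:
        feats = self.features()
        lines = [f"Muscle synergies (N = {self.n_synergies})",
                 f"reconstruction quality  {self.reconstruction_quality:.2f} %",
                 f"{'synergy':<10}{'peak level':>12}{'peak time %':>13}{'dominant':>10}"]
        for j in range(self.n_synergies):
            dom = self.muscle_labels[int(np.argmax(self.W[:, j]))]
            lines.append(f"{j + 1:<10}{feats['peak_level'][j]:>12.4f}"
                         f"{feats['peak_time_pct'][j]:>13.1f}{dom:>10}")
        return "\n".join(lines)


class SynergyModel:
    """Model: trial activation matrix in, fitted synergy set out."""

    def __init__(self, M: np.ndarray, n_synergies: int = DEFAULT_N_SYNERGIES,
                 muscle_labels: tuple[str, ...] = MEASURED_MUSCLES,
                 progress: np.ndarray | None = None):
        self.M = np.asarray(M, dtype=float)
        self.n_synergies = n_synergies
        self.muscle_labels = tuple(muscle_labels)[: self.M.shape[0]]
        self.progress = (np.linspace(0, 100, self.M.shape[1])
                         if progress is None else np.asarray(progress, dtype=float))

    def fit(self, seed: int = 0, restarts: int = 20, max_iter: int = 2000,
            tol: float = 1e-6) -> SynergyResult:
        W, C, errors = extract_synergies(self.M, self.n_synergies, seed=seed,
                                         restarts=restarts, max_iter=max_iter, tol=tol)
        return SynergyResult(
            W=W, C=C, n_synergies=self.n_synergies,
            reconstruction_quality=reconstruction_quality(self.M, W, C),
            muscle_labels=self.muscle_labels, progress=self.progress,
            seed=seed, restarts=restarts, error_trace=errors,
        )


# ---------------------------------------------------------------------------
# cross-trial matching
# ---------------------------------------------------------------------------

def default_spatial_templates(labels: tuple[str, ...] = MEASURED_MUSCLES) -> np.ndarray:
    """Phase-ordered spatial reference templates for synergy matching.

    Dominant muscles per phase: RA (body flexion), TA (hip raise),
    VAS + ES (body extension), SOL (posture control).
    """
    dominant = ({"RA": 1.0}, {"TA": 1.0}, {"VAS": 1.0, "ES": 0.9}, {"SOL": 1.0})
    W = np.full((len(labels), len(dominant)), 0.05)
    for j, weights in enumerate(dominant):
        for name, w in weights.items():
            if name in labels:
                W[labels.index(name), j] = w
    return W


def match_synergies(candidate_W: np.ndarray, reference_W: np.ndarray) -> np.ndarray:
    """Permutation aligning candidate synergy columns to a reference.

    Greedy assignment on the cosine-similarity matrix (largest similarity
    first, ties by index).  ``permutation[j]`` is the candidate column that
    plays the role of reference synergy ``j``.
    """
    cand = np.asarray(candidate_W, dtype=float)
    ref = np.asarray(reference_W, dtype=float)
    if cand.shape != ref.shape:
        raise ValidationError("candidate and reference must have equal shapes")
    n = cand.shape[1]

    def unit(X):
        norms = np.linalg.norm(X, axis=0)
        return X / np.maximum(norms, _EPS)[None, :]

    sim = unit(ref).T @ unit(cand)                      # (ref j, cand i)
    perm = np.full(n, -1)
    used = np.zeros(n, dtype=bool)
    order = np.argsort(-sim, axis=None, kind="stable")
    for flat in order:
        j, i = divmod(int(flat), n)
        if perm[j] == -1 and not used[i]:
            perm[j] = i
            used[i] = True
    return perm


# ---------------------------------------------------------------------------
# longitudinal statistics
# ---------------------------------------------------------------------------

def longitudinal_stats(groups: list[np.ndarray]) -> tuple[float, float, str]:
    """Nonparametric comparison of a feature across session days.

    Two groups: two-sided Wilcoxon rank-sum; three or more: Kruskal-Wallis.
    Each group needs at least two trials.  Returns (statistic, p, test name).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two session-day groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each session-day group needs at least two trials")
    if len(groups) == 2:
        stat, p = stats.ranksums(groups[0], groups[1])
        return float(stat), float(p), "wilcoxon_rank_sum"
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p), "kruskal_wallis"


def percent_change(first: float, last: float) -> float:
    """Relative change of a feature between first and last session, percent."""
    if first == 0:
        raise ValidationError("percent change undefined for a zero baseline")
    return 100.0 * (last - first) / first


def longitudinal_feature_table(day_features: list[np.ndarray],
                               labels: list[str]) -> list[dict]:
    """Per-feature statistics across days.

    ``day_features`` is a list over days of (n_trials, n_features) arrays.
    Percent change uses the per-day mean of per-trial values (first vs last
    day).  Returns one record per feature with the test statistic, p-value
    and percent change.
    """
    if len(day_features) < 2:
        raise ValidationError("need at least two session days")
    records = []
    for j, label in enumerate(labels):
        groups = [np.asarray(day)[:, j] for day in day_features]
        stat, p, test = longitudinal_stats(groups)
        first = float(np.mean(groups[0]))
        last = float(np.mean(groups[-1]))
        records.append({
            "feature": label,
            "n_days": len(groups),
            "test": test,
            "statistic": stat,
            "p_value": p,
            "percent_change": percent_change(first, last) if first != 0 else float("nan"),
        })
    return records
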