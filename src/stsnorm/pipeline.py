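"""End-to-end orchestration: preprocess -> inverse dynamics -> normalization
-> tensions -> synergies -> longitudinal statistics.

One call of :func:`run_pipeline` processes a set of per-trial manifests for
a subject, fits the torque-based normalization per trial, extracts and
phase-matches four synergies per trial, and aggregates per-day feature
distributions into a summary table (muscle rows: maximum tension; synergy
rows: temporal peak level) with nonparametric tests and percent changes.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body import BodyModel, JOINTS
from .dynamics import ExternalForces, differentiate_kinematics, inverse_dynamics
from .errors import StsnormError, ValidationError
from .io import load_recording, provenance, write_table
from .muscles import MEASURED_MUSCLES, MuscleSet, muscle_kinematics, muscle_tension
from .normalization import NormalizationResult, TorqueNormalization
from .preprocessing import ProcessedTrial, preprocess_trial
from .synergy import (
    DEFAULT_N_SYNERGIES,
    SynergyModel,
    default_spatial_templates,
    longitudinal_feature_table,
    match_synergies,
)

logger = logging.getLogger("stsnorm")

#: significance thresholds used in the summary flags
P_TENSION = 0.001
P_SYNERGY = 0.05


@dataclass
class PipelineConfig:
    """Paths, seed and options threaded through the pipeline."""

    body_yaml: str | None = None
    muscles_yaml: str | None = None
    out_dir: str = "stsnorm_out"
    seed: int = 0
    n_synergies: int = DEFAULT_N_SYNERGIES
    nnmf_restarts: int = 20
    height: float = 1.70
    mass: float = 65.0
    verbose: bool = False

    def body(self) -> BodyModel:
        if self.body_yaml:
            return BodyModel.from_yaml(self.body_yaml, self.height, self.mass)
        return BodyModel.from_anthropometry(self.height, self.mass)

    def muscle_set(self) -> MuscleSet:
        return MuscleSet.from_yaml(self.muscles_yaml) if self.muscles_yaml else MuscleSet.default()


@dataclass
class TrialResult:
    """All per-trial artifacts produced by the pipeline."""

    session_day: int
    processed: ProcessedTrial
    torques: np.ndarray
    normalization: NormalizationResult
    max_tension: dict[str, float]
    synergy_peaks: np.ndarray
    synergy_quality: float


def analyze_processed_trial(trial: ProcessedTrial, body: BodyModel,
                            muscles: MuscleSet, config: PipelineConfig) -> TrialResult:
    """Inverse dynamics, normalization, tensions and synergies for one trial."""
    window_rate = (len(trial.progress) - 1) / (trial.window[1] - trial.window[0])
    kin = differentiate_kinematics(trial.angle_matrix(on_progress=True),
                                   rate=window_rate, smoothing_window=5)
    hip_y = trial.progress_forces["hip"].copy()
    t_abs = trial.window[0] + (trial.window[1] - trial.window[0]) * trial.progress / 100.0
    hip_y[t_abs >= trial.seat_off_time] = 0.0
    hip_x = trial.progress_forces.get("hip_x", np.zeros_like(hip_y))
    ext = ExternalForces(hip=np.column_stack([hip_x, hip_y]))
    torques = inverse_dynamics(kin, ext, body)

    model = TorqueNormalization.from_processed_trial(trial, torques, kin, muscles=muscles)
    norm = model.fit(seed=config.seed)
    if not norm.converged:
        logger.warning("normalization solver did not report convergence")
    clipped = np.isclose(norm.activation.max(axis=0), 1.0).sum()
    if clipped:
        logger.warning("%d muscle(s) at the activation bound", clipped)

    max_tension = {}
    for i, params in enumerate(muscles):
        state = muscle_kinematics(kin.theta, kin.omega, params)
        tension = muscle_tension(params, state, norm.activation[:, i])
        max_tension[params.name] = float(tension.total.max())

    measured = [n for n in muscles.names if n in trial.progress_envelopes]
    M = norm.activation[:, : len(measured)].T
    syn = SynergyModel(M, n_synergies=config.n_synergies,
                       muscle_labels=tuple(measured), progress=trial.progress)
    res = syn.fit(seed=config.seed, restarts=config.nnmf_restarts)
    perm = match_synergies(res.W, default_spatial_templates(tuple(measured)))
    res = res.reorder(perm)
    return TrialResult(
        session_day=trial.session_day, processed=trial, torques=torques,
        normalization=norm, max_tension=max_tension,
        synergy_peaks=res.features()["peak_level"],
        synergy_quality=res.reconstruction_quality,
    )


def run_pipeline(manifests: list[str | Path], config: PipelineConfig) -> pd.DataFrame:
    """Process all trial manifests for one subject and write the report bundle.

    Returns the summary table (one row per muscle feature and per synergy
    feature: test, statistic, p-value, percent change, significance flag).
    Trials that fail any stage are skipped with a logged reason.
    """
    if not manifests:
        raise ValidationError("empty manifest list")
    body = config.body()
    muscles = config.muscle_set()
    results: list[TrialResult] = []
    failures = 0
    for path in manifests:
        t0 = _time.perf_counter()
        try:
            recording = load_recording(path)
            trial = preprocess_trial(recording)
            results.append(analyze_processed_trial(trial, body, muscles, config))
            logger.info("trial %s done in %.2f s", path, _time.perf_counter() - t0)
        except StsnormError as exc:
            failures += 1
            logger.error("trial %s aborted: %s", path, exc)
    if not results:
        raise ValidationError("no trial completed successfully")

    summary = summarize(results, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(summary, out / "summary.tsv")
    meta = provenance(seed=config.seed, config=vars(config))
    meta.update({"n_trials_completed": len(results), "n_trials_failed": failures})
    pd.Series(meta).to_json(out / "provenance.json", indent=2)
    return summary


def summarize(results: list[TrialResult], config: PipelineConfig) -> pd.DataFrame:
    """Per-day feature distributions -> tests, percent change, significance."""
    days = sorted({r.session_day for r in results})
    rows = []
    if len(days) >= 2:
        tension_by_day = [
            np.array([[r.max_tension[m] for m in MEASURED_MUSCLES]
                      for r in results if r.session_day == d])
            for d in days
        ]
        for rec in longitudinal_feature_table(tension_by_day, list(MEASURED_MUSCLES)):
            rec.update(kind="max_muscle_tension",
                       significant=rec["p_value"] < P_TENSION)
            rows.append(rec)
        peaks_by_day = [
            np.array([r.synergy_peaks for r in results if r.session_day == d])
            for d in days
        ]
        labels = [f"synergy_{j + 1}" for j in range(config.n_synergies)]
        for rec in longitudinal_feature_table(peaks_by_day, labels):
            rec.update(kind="synergy_peak_level",
                       significant=rec["p_value"] < P_SYNERGY)
            rows.append(rec)
    else:  # single day: descriptive rows only
        for m in MEASURED_MUSCLES:
            vals = [r.max_tension[m] for r in results]
            rows.append({"feature": m, "kind": "max_muscle_tension",
                         "n_days": 1, "test": "none", "statistic": float("nan"),
                         "p_value": float("nan"),
                         "percent_change": float("nan"), "significant": False,
                         "mean": float(np.mean(vals))})
        for j in range(config.n_synergies):
            vals = [r.synergy_peaks[j] for r in results]
            rows.append({"feature": f"synergy_{j + 1}", "kind": "synergy_peak_level",
                         "n_days": 1, "test": "none", "statistic": float("nan"),
                         "p_value": float("nan"),
                         "percent_change": float("nan"), "significant": False,
                         "mean": float(np.mean(vals))})
    return pd.DataFrame(rows)
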