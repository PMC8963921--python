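"""Signal conditioning, seat-off detection and trial segmentation.

EMG recorded during sit-to-stand is band-pass filtered (40-400 Hz, zero-lag
4th-order Butterworth), full-wave rectified and smoothed with a 4 Hz
low-pass Butterworth into a non-negative envelope.  Force-plate channels
are low-pass filtered at 20 Hz.  Seat-off is the first instant the hip
vertical force drops below 10 N, and a trial is the 3-second window from
one second before seat-off to two seconds after.  All streams are resampled
to a common 100 Hz base (the kinematics rate) plus a fixed 0-100 % motion
progress grid.

Synthetic or pre-enveloped recordings carry ``emg_domain="envelope"``; for
those the band-pass/rectification stages are skipped and only the 4 Hz
smoothing is applied, since the signal is already an amplitude envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .body import JOINTS
from .errors import (
    InvalidLoadingError,
    NoSeatOffError,
    TruncationError,
    UnsupportedRateError,
    ValidationError,
)
from .muscles import MEASURED_MUSCLES

SEAT_OFF_THRESHOLD_N = 10.0
WINDOW_BEFORE_S = 1.0
WINDOW_AFTER_S = 2.0
DEFAULT_COMMON_RATE = 100.0
DEFAULT_PROGRESS_SAMPLES = 101

EMG_BAND_HZ = (40.0, 400.0)
EMG_SMOOTH_HZ = 4.0
FORCE_LOWPASS_HZ = 20.0
_FILTER_ORDER = 4


@dataclass
class TrialRecording:
    """Raw multirate streams for one sit-to-stand trial.

    ``emg``, ``forces`` and ``angles`` map channel label -> 1-D array;
    ``rates`` gives the sample rate (Hz) per stream name.  ``forces`` must
    contain a ``hip`` vertical-force channel; optional ``hip_x``,
    ``lfoot``/``rfoot`` channels are carried through.
    """

    emg: dict[str, np.ndarray]
    forces: dict[str, np.ndarray]
    angles: dict[str, np.ndarray]
    rates: dict[str, float]
    subject_id: str = "anonymous"
    session_day: int = 0
    emg_domain: str = "raw"

    def __post_init__(self) -> None:
        for stream in ("emg", "force", "angles"):
            if self.rates.get(stream, 0) <= 0:
                raise ValidationError(f"sample rate for '{stream}' must be positive")
        unknown = set(self.emg) - set(MEASURED_MUSCLES)
        if unknown:
            raise ValidationError(f"unknown EMG channels: {sorted(unknown)}")
        if set(self.angles) != set(JOINTS):
            raise ValidationError(f"angle channels must be exactly {JOINTS}")
        if "hip" not in self.forces:
            raise ValidationError("forces must include a 'hip' vertical channel")
        if self.emg_domain not in ("raw", "envelope"):
            raise ValidationError("emg_domain must be 'raw' or 'envelope'")
        for group in (self.emg, self.forces, self.angles):
            lengths = {len(v) for v in group.values()}
            if len(lengths) > 1:
                raise ValidationError("series within a stream must share length")


@dataclass
class ProcessedTrial:
    """Conditioned, segmented trial on a common time base.

    ``time`` spans the 3-s window (seat-off at the 1-s mark); ``progress``
    is the 0-100 % grid.  ``envelopes``/``angles``/``forces`` are sampled on
    ``time``; the ``progress_*`` twins are resampled onto ``progress``.
    """

    time: np.ndarray
    envelopes: dict[str, np.ndarray]
    angles: dict[str, np.ndarray]
    forces: dict[str, np.ndarray]
    seat_off_time: float
    window: tuple[float, float]
    progress: np.ndarray
    progress_envelopes: dict[str, np.ndarray]
    progress_angles: dict[str, np.ndarray]
    progress_forces: dict[str, np.ndarray]
    rate: float = DEFAULT_COMMON_RATE
    subject_id: str = "anonymous"
    session_day: int = 0

    def envelope_matrix(self, order: tuple[str, ...] = MEASURED_MUSCLES,
                        on_progress: bool = True) -> np.ndarray:
        src = self.progress_envelopes if on_progress else self.envelopes
        return np.column_stack([src[name] for name in order if name in src])

    def angle_matrix(self, on_progress: bool = True) -> np.ndarray:
        src = self.progress_angles if on_progress else self.angles
        return np.column_stack([src[j] for j in JOINTS])


def _check_series(x: np.ndarray, name: str = "series") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError(f"empty {name}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"non-finite samples in {name}")
    return x


def _zero_lag_filter(x: np.ndarray, rate: float, cutoff, btype: str) -> np.ndarray:
    sos = signal.butter(_FILTER_ORDER, cutoff, btype=btype, fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def emg_envelope(raw: np.ndarray, rate: float, domain: str = "raw") -> np.ndarray:
    """Non-negative EMG amplitude envelope.

    ``raw`` mode applies the 40-400 Hz zero-lag band-pass, full-wave
    rectification and a 4 Hz low-pass; ``envelope`` mode (pre-enveloped
    input) applies only the 4 Hz smoothing.  The result is clipped at zero
    since the Butterworth low-pass can undershoot slightly.
    """
    x = _check_series(raw, "EMG channel")
    if domain == "raw":
        if rate <= 2 * EMG_BAND_HZ[1]:
            raise UnsupportedRateError(
                f"EMG rate {rate} Hz too low for a {EMG_BAND_HZ[1]} Hz band edge")
        if EMG_BAND_HZ[1] >= 0.75 * rate / 2:
            warnings.warn(
                f"band edge {EMG_BAND_HZ[1]} Hz is at {EMG_BAND_HZ[1] / (rate / 2):.2f} "
                "of Nyquist; filter response is compressed", RuntimeWarning, stacklevel=2)
        x = _zero_lag_filter(x, rate, EMG_BAND_HZ, "bandpass")
        x = np.abs(x)
    elif domain == "envelope":
        if rate <= 2 * EMG_SMOOTH_HZ:
            raise UnsupportedRateError("rate too low for the 4 Hz smoothing filter")
        if np.any(x < 0):
            raise ValidationError("pre-enveloped EMG must be non-negative")
    else:
        raise ValidationError("domain must be 'raw' or 'envelope'")
    env = _zero_lag_filter(x, rate, EMG_SMOOTH_HZ, "lowpass")
    return np.clip(env, 0.0, None)


def filter_forces(force: np.ndarray, rate: float) -> np.ndarray:
    """Zero-lag 20 Hz low-pass (4th-order Butterworth) for force-plate data."""
    x = _check_series(force, "force channel")
    if rate <= 2 * FORCE_LOWPASS_HZ:
        raise UnsupportedRateError(f"force rate {rate} Hz too low for a 20 Hz low-pass")
    return _zero_lag_filter(x, rate, FORCE_LOWPASS_HZ, "lowpass")


def detect_seat_off(hip_vertical: np.ndarray, rate: float,
                    threshold: float = SEAT_OFF_THRESHOLD_N,
                    min_loaded_s: float = 0.2) -> float:
    """Time (s) of the first sample where hip force drops below ``threshold``.

    The recording must start with at least ``min_loaded_s`` seconds of
    loading above the threshold (guards against starting unloaded).
    """
    x = _check_series(hip_vertical, "hip force")
    n_loaded = int(round(min_loaded_s * rate))
    if len(x) <= n_loaded:
        raise ValidationError("hip-force series shorter than the required loaded prefix")
    if np.any(x[:n_loaded] < threshold):
        raise InvalidLoadingError("recording starts with the hip unloaded")
    below = np.nonzero(x[n_loaded:] < threshold)[0]
    if below.size == 0:
        raise NoSeatOffError(f"hip force never drops below {threshold} N")
    return (n_loaded + below[0]) / rate


def _resample(x: np.ndarray, rate: float, t_new: np.ndarray) -> np.ndarray:
    t_old = np.arange(len(x)) / rate
    return np.interp(t_new, t_old, x)


def segment_trial(
    emg_env: dict[str, np.ndarray],
    forces: dict[str, np.ndarray],
    angles: dict[str, np.ndarray],
    rates: dict[str, float],
    seat_off_time: float,
    common_rate: float = DEFAULT_COMMON_RATE,
    progress_samples: int = DEFAULT_PROGRESS_SAMPLES,
    subject_id: str = "anonymous",
    session_day: int = 0,
) -> ProcessedTrial:
    """Cut all streams to the 3-s trial window and resample to common bases.

    The window is ``[seat_off - 1 s, seat_off + 2 s]``, sampled inclusively
    at ``common_rate`` (301 samples at 100 Hz) and on a 0-100 % progress
    grid of ``progress_samples`` points.
    """
    t0 = seat_off_time - WINDOW_BEFORE_S
    t1 = seat_off_time + WINDOW_AFTER_S
    durations = [
        (len(next(iter(group.values()))) - 1) / rates[stream]
        for group, stream in ((emg_env, "emg"), (forces, "force"), (angles, "angles"))
        if group
    ]
    if t0 < -1e-9 or any(t1 > d + 1e-9 for d in durations):
        raise TruncationError(
            f"window [{t0:.3f}, {t1:.3f}] s exceeds the recording bounds")
    n_win = int(round((t1 - t0) * common_rate)) + 1
    time = t0 + np.arange(n_win) / common_rate
    progress = np.linspace(0.0, 100.0, progress_samples)
    t_prog = t0 + (t1 - t0) * progress / 100.0

    def cut(group: dict[str, np.ndarray], rate: float):
        win = {k: _resample(v, rate, time) for k, v in group.items()}
        prog = {k: _resample(v, rate, t_prog) for k, v in group.items()}
        return win, prog

    env_w, env_p = cut(emg_env, rates["emg"])
    for k in env_w:
        env_w[k] = np.clip(env_w[k], 0.0, None)
        env_p[k] = np.clip(env_p[k], 0.0, None)
    frc_w, frc_p = cut(forces, rates["force"])
    ang_w, ang_p = cut(angles, rates["angles"])
    return ProcessedTrial(
        time=time, envelopes=env_w, angles=ang_w, forces=frc_w,
        seat_off_time=seat_off_time, window=(t0, t1),
        progress=progress, progress_envelopes=env_p,
        progress_angles=ang_p, progress_forces=frc_p,
        rate=common_rate, subject_id=subject_id, session_day=session_day,
    )


def mvc_normalize(envelope: np.ndarray, mvc_value: float) -> np.ndarray:
    """Scale an envelope by a per-muscle MVC reference (healthy-subject mode).

    Values above 1 are permitted (activation exceeding the MVC reference)
    and flagged with a warning.
    """
    if mvc_value <= 0:
        raise ValidationError("MVC value must be positive")
    out = np.asarray(envelope, dtype=float) / mvc_value
    if np.any(out > 1.0):
        warnings.warn("MVC-normalized envelope exceeds 1.0", RuntimeWarning, stacklevel=2)
    return out


def preprocess_trial(recording: TrialRecording,
                     common_rate: float = DEFAULT_COMMON_RATE,
                     progress_samples: int = DEFAULT_PROGRESS_SAMPLES,
                     mvc: dict[str, float] | None = None) -> ProcessedTrial:
    """Full conditioning chain: envelopes, force filtering, seat-off, segmentation.

    Seat-off is detected on the *filtered* hip force.  When ``mvc`` is given
    (healthy-reference mode) each envelope is additionally divided by its
    per-muscle MVC value; by default the MVC peak is taken from the
    recording passed in (within-trial convention).
    """
    env = {name: emg_envelope(x, recording.rates["emg"], recording.emg_domain)
           for name, x in recording.emg.items()}
    if mvc is not None:
        env = {name: mvc_normalize(x, mvc[name]) for name, x in env.items()}
    frc = {name: filter_forces(x, recording.rates["force"])
           for name, x in recording.forces.items()}
    seat_off = detect_seat_off(frc["hip"], recording.rates["force"])
    return segment_trial(
        env, frc, recording.angles, recording.rates, seat_off,
        common_rate=common_rate, progress_samples=progress_samples,
        subject_id=recording.subject_id, session_day=recording.session_day,
    )
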