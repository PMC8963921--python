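"""Reading and writing of trial streams, manifests and result tables.

Streams are delimited text: one CSV per stream with a ``time_s`` first
column and labeled channel columns, tied together by a per-trial YAML/JSON
manifest.  Processed trials serialize to a directory of TSVs plus a
``meta.json``.  Floats are written with 12 significant digits so that
write -> read round-trips are lossless at analysis precision; parsing is
locale-independent (dot decimal only).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .preprocessing import ProcessedTrial, TrialRecording

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path, required: tuple[str, ...] = (),
               sep: str = "\t") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _stream_frame(time: np.ndarray, channels: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame({"time_s": time, **channels})


def write_stream_csv(path: str | Path, rate: float,
                     channels: dict[str, np.ndarray]) -> None:
    n = len(next(iter(channels.values())))
    write_table(_stream_frame(np.arange(n) / rate, channels), path, sep=",")


def read_stream_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = read_table(path, required=("time_s",), sep=",")
    return {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}


# ---------------------------------------------------------------------------
# manifest + raw recording
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    for key in ("emg", "forces", "angles", "rates"):
        if key not in manifest:
            raise ValidationError(f"manifest {path}: missing '{key}'")
    return manifest


def load_recording(manifest_path: str | Path) -> TrialRecording:
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    return TrialRecording(
        emg=read_stream_csv(root / manifest["emg"]),
        forces=read_stream_csv(root / manifest["forces"]),
        angles=read_stream_csv(root / manifest["angles"]),
        rates={k: float(v) for k, v in manifest["rates"].items()},
        subject_id=str(manifest.get("subject_id", "anonymous")),
        session_day=int(manifest.get("session_day", 0)),
        emg_domain=manifest.get("emg_domain", "raw"),
    )


def write_recording(recording: TrialRecording, out_dir: str | Path,
                    name: str = "trial") -> Path:
    """Write a recording as the CSV + manifest layout preprocessing consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stream_csv(out / f"{name}_emg.csv", recording.rates["emg"], recording.emg)
    write_stream_csv(out / f"{name}_forces.csv", recording.rates["force"], recording.forces)
    write_stream_csv(out / f"{name}_angles.csv", recording.rates["angles"], recording.angles)
    manifest = {
        "emg": f"{name}_emg.csv", "forces": f"{name}_forces.csv",
        "angles": f"{name}_angles.csv",
        "rates": {k: float(v) for k, v in recording.rates.items()},
        "subject_id": recording.subject_id, "session_day": recording.session_day,
        "emg_domain": recording.emg_domain,
    }
    manifest_path = out / f"{name}.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


# ---------------------------------------------------------------------------
# processed trials
# ---------------------------------------------------------------------------

def save_processed(trial: ProcessedTrial, out_dir: str | Path,
                   provenance: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(_stream_frame(trial.time, trial.envelopes), out / "envelopes.tsv")
    write_table(_stream_frame(trial.time, trial.angles), out / "angles.tsv")
    write_table(_stream_frame(trial.time, trial.forces), out / "forces.tsv")
    meta = {
        "seat_off_time": trial.seat_off_time,
        "window": list(trial.window),
        "rate": trial.rate,
        "progress_samples": len(trial.progress),
        "subject_id": trial.subject_id,
        "session_day": trial.session_day,
        "provenance": provenance or {},
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_processed(in_dir: str | Path) -> ProcessedTrial:
    from .preprocessing import segment_trial

    root = Path(in_dir)
    with open(root / "meta.json") as fh:
        meta = json.load(fh)

    def load(name):
        df = read_table(root / name, required=("time_s",))
        return {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}

    env, ang, frc = load("envelopes.tsv"), load("angles.tsv"), load("forces.tsv")
    rate = float(meta["rate"])
    # re-segment around the stored window (idempotent on an exact window)
    n = len(next(iter(ang.values())))
    offset = meta["window"][0]
    shifted_seat_off = meta["seat_off_time"] - offset
    trial = segment_trial(
        env, frc, ang, {"emg": rate, "force": rate, "angles": rate},
        shifted_seat_off, common_rate=rate,
        progress_samples=int(meta["progress_samples"]),
        subject_id=meta.get("subject_id", "anonymous"),
        session_day=int(meta.get("session_day", 0)),
    )
    trial.seat_off_time = meta["seat_off_time"]
    trial.window = tuple(meta["window"])
    trial.time = trial.time + offset
    return trial


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Metadata block stamped into every output file."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "package": "stsnorm",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
    }
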