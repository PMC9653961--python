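"""File formats: 16-bit PCM WAV voice files, EMG CSV traces, cohort manifests.

Voice recordings are mono 16-bit PCM WAV named ``<subject>_<tone>_<trial>.wav``;
EMG traces are CSV with header ``time_s,amplitude_uv`` named
``<subject>_<tone>_emg.csv``.  The cohort manifest is a CSV keyed by subject
with group, lesion side and demographics.  Generator and analyzer parameters
are echoed to JSON sidecars for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustic import VoiceRecording
from .emg import EMGRecording

__all__ = [
    "write_wav",
    "read_wav",
    "write_emg_csv",
    "read_emg_csv",
    "read_manifest",
    "validate_manifest",
    "write_json_sidecar",
    "voice_filename",
    "emg_filename",
]

MANIFEST_COLUMNS = ["subject_id", "group", "lesion_side", "age", "months_post_paralysis", "etiology"]
GROUP_LABELS = ("CT+", "CT-")


def voice_filename(subject_id: str, tone: int, trial: int) -> str:
    return f"{subject_id}_{tone}_{trial}.wav"


def emg_filename(subject_id: str, tone: int) -> str:
    return f"{subject_id}_{tone}_emg.csv"


def write_wav(path, rec: VoiceRecording) -> None:
    """Write samples (expected within [-1, 1]) as mono 16-bit PCM."""
    x = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(str(path), int(rec.fs), np.round(x * 32767).astype(np.int16))


def read_wav(path, subject_id: str = "", tone: int = 1, trial: int = 1) -> VoiceRecording:
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV")
    if data.dtype == np.int16:
        samples = data / 32767.0
    elif data.dtype == np.int32:
        samples = data / 2147483647.0
    else:
        samples = data.astype(float)
    return VoiceRecording(samples=samples, fs=float(fs), subject_id=subject_id,
                          tone=tone, trial=trial)


def write_emg_csv(path, rec: EMGRecording) -> None:
    t = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": t, "amplitude_uv": rec.samples}).to_csv(path, index=False)


def read_emg_csv(path, subject_id: str = "", muscle: str = "CT",
                 side: str = "lesion", tone: int = 1) -> EMGRecording:
    df = pd.read_csv(path)
    if not {"time_s", "amplitude_uv"}.issubset(df.columns):
        raise ValueError(f"{path}: EMG CSV needs columns time_s,amplitude_uv")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: EMG trace too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError(f"{path}: non-uniform sampling")
    return EMGRecording(samples=df["amplitude_uv"].to_numpy(), fs=1.0 / dt[0],
                        subject_id=subject_id, muscle=muscle, side=side, tone=tone)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dup}")
    bad = sorted(set(df["group"]) - set(GROUP_LABELS))
    if bad:
        raise ValueError(f"invalid group labels {bad}; expected {GROUP_LABELS}")


def write_json_sidecar(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
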