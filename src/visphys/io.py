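"""Readers and writers for the on-disk formats.

Conventions: CSV for tabular data, JSON for models and specs, little-endian
float32 binary with a JSON sidecar for arrays.  All times are ms, angles
degrees, screen coordinates degrees relative to fixation unless a column is
suffixed ``_px``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eye_tracking import GazeSamples
from .neural_preproc import EpochSet, RawRecording

__all__ = [
    "write_raw_recording",
    "read_raw_recording",
    "write_epochs",
    "read_epochs",
    "write_gaze",
    "read_gaze",
    "write_trials",
    "read_trials",
]


def write_raw_recording(rec: RawRecording, path) -> None:
    """Channel-major little-endian float32 + JSON sidecar (.json)."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = {
        "fs": rec.fs,
        "n_channels": int(rec.n_channels),
        "shank_map": [str(s) for s in rec.shank_map],
        "units": "uV",
        "dtype": "<f4",
        "order": "channel_major",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_recording(path) -> RawRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    flat = np.fromfile(path, dtype="<f4")
    samples = flat.reshape(sidecar["n_channels"], -1).astype(float)
    return RawRecording(samples=samples, fs=sidecar["fs"], shank_map=np.array(sidecar["shank_map"]))


def write_epochs(epochs: EpochSet, path) -> None:
    """Epoch data as float32 binary + JSON header."""
    path = Path(path)
    epochs.data.astype("<f4").tofile(path)
    header = {
        "shape": list(epochs.data.shape),
        "window_ms": [-epochs.pre_ms, epochs.post_ms],
        "fs": epochs.fs,
        "condition_ids": [str(c) for c in epochs.condition_ids],
        "onset_ms": epochs.onset_ms.tolist(),
        "valid": epochs.valid.astype(int).tolist(),
        "dtype": "<f4",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def read_epochs(path) -> EpochSet:
    path = Path(path)
    h = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<f4").reshape(h["shape"]).astype(float)
    return EpochSet(
        data=data,
        condition_ids=np.array(h["condition_ids"], dtype=object),
        onset_ms=np.array(h["onset_ms"], dtype=float),
        valid=np.array(h["valid"], dtype=bool),
        fs=h["fs"],
        pre_ms=-h["window_ms"][0],
        post_ms=h["window_ms"][1],
    )


def write_gaze(gaze: GazeSamples, path) -> None:
    pd.DataFrame(
        {"time_ms": gaze.t_ms, "x": gaze.x, "y": gaze.y, "valid": gaze.valid.astype(int)}
    ).to_csv(path, index=False)


def read_gaze(path, unit: str = "raw") -> GazeSamples:
    df = pd.read_csv(path)
    return GazeSamples(
        t_ms=df["time_ms"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        valid=df["valid"].to_numpy(dtype=bool),
        unit=unit,
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    if Path(path).stat().st_size == 0:
        raise ValueError(f"trials file {path} is empty")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"trials file {path} contains no trials")
    return df
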