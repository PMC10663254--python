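"""Reading and writing the package's signal containers.

Recordings and trial sets travel as HDF5 files with attributes for the
acquisition metadata; small fixtures can round-trip through CSV plus a JSON
sidecar instead.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EvokedTrialSet, LfpRecording


def save_recording(path: str | Path, rec: LfpRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples, track_times=False)
        d.attrs["units"] = "uV"
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["highpass_corner"] = rec.highpass_corner
        f.create_dataset("channel_ids", data=np.asarray(rec.channel_ids), track_times=False)
        f.attrs["metadata"] = json.dumps(rec.metadata, default=str, sort_keys=True)


def load_recording(path: str | Path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        return LfpRecording(
            samples=f["samples"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            highpass_corner=float(f.attrs["highpass_corner"]),
            channel_ids=[int(c) for c in f["channel_ids"][...]],
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def recording_to_csv(path: str | Path, rec: LfpRecording) -> None:
    """One column per channel; metadata in a ``<stem>.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=[f"ch{c}" for c in rec.channel_ids])
    df.to_csv(path, index=False)
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "highpass_corner": rec.highpass_corner,
        "units": "uV",
        "channel_ids": list(rec.channel_ids),
        "metadata": rec.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, default=str, indent=1))


def recording_from_csv(path: str | Path) -> LfpRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    return LfpRecording(
        samples=df.to_numpy().T,
        sampling_rate=float(sidecar["sampling_rate"]),
        highpass_corner=float(sidecar.get("highpass_corner", 0.1)),
        channel_ids=[int(c) for c in sidecar["channel_ids"]],
        metadata=sidecar.get("metadata", {}),
    )


def save_trialset(path: str | Path, ts: EvokedTrialSet) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("epochs", data=ts.epochs, track_times=False)
        d.attrs["units"] = "uV"
        f.create_dataset("times_ms", data=ts.times_ms, track_times=False)
        f.attrs["sampling_rate"] = ts.sampling_rate
        f.attrs["intensity_ua"] = ts.intensity_ua


def load_trialset(path: str | Path) -> EvokedTrialSet:
    with h5py.File(path, "r") as f:
        return EvokedTrialSet(
            epochs=f["epochs"][...],
            times_ms=f["times_ms"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            intensity_ua=float(f.attrs["intensity_ua"]),
        )


def intervals_to_csv(path: str | Path, intervals) -> None:
    """Write a (state, start_s, end_s) interval table."""
    pd.DataFrame(intervals, columns=["state", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def intervals_from_csv(path: str | Path) -> list[tuple[int, float, float]]:
    df = pd.read_csv(path)
    return [
        (int(s), float(a), float(b))
        for s, a, b in zip(df["state"], df["start_s"], df["end_s"])
    ]
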