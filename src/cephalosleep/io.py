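"""Readers and writers for the package's on-disk formats.

Traces are CSV (``time_s,value``) or HDF5 (``/trace`` with an ``fps``
attribute); LFP recordings are HDF5 (``/lfp`` channels x samples float32
microvolts plus a ``/channels`` table); schedules and event lists are CSV;
ground truth is a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (BrightnessTrace, LFPRecording, MovementTrace,
                        PatternTrajectory, StateSchedule, SyntheticTruth)

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_trace_h5", "read_trace_h5",
    "write_lfp_h5", "read_lfp_h5",
    "write_schedule_csv", "read_schedule_csv",
    "write_events_csv", "read_events_csv",
    "write_truth_json", "read_truth_json",
    "write_features_h5", "read_features_h5",
]


# --------------------------------------------------------------------------- #
# traces

def write_trace_csv(path, trace) -> None:
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(path, index=False)


def read_trace_csv(path, kind: str = "brightness"):
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fps = 1.0 / np.median(np.diff(t))
    cls = BrightnessTrace if kind == "brightness" else MovementTrace
    return cls(values=df["value"].to_numpy(), fps=fps, t0=float(t[0]))


def write_trace_h5(path, trace) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=trace.values)
        d.attrs["fps"] = trace.fps
        d.attrs["t0"] = trace.t0


def read_trace_h5(path, kind: str = "brightness"):
    with h5py.File(path, "r") as f:
        d = f["trace"]
        cls = BrightnessTrace if kind == "brightness" else MovementTrace
        return cls(values=d[()], fps=float(d.attrs["fps"]),
                   t0=float(d.attrs.get("t0", 0.0)))


# --------------------------------------------------------------------------- #
# LFP

def write_lfp_h5(path, rec: LFPRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=rec.data.astype(np.float32))
        d.attrs["fs_Hz"] = rec.fs_Hz
        g = f.create_group("channels")
        for col in rec.channels.columns:
            vals = rec.channels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)


def read_lfp_h5(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        data = f["lfp"][()]
        fs = float(f["lfp"].attrs["fs_Hz"])
        cols = {}
        for name, d in f["channels"].items():
            v = d[()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[name] = v
        return LFPRecording(data=data, fs_Hz=fs, channels=pd.DataFrame(cols))


# --------------------------------------------------------------------------- #
# schedules and event lists

def write_schedule_csv(path, schedule: StateSchedule) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule_csv(path) -> StateSchedule:
    return StateSchedule.from_frame(pd.read_csv(path))


def write_events_csv(path, times_s, labels=None) -> None:
    df = pd.DataFrame({"time_s": np.asarray(times_s, dtype=float)})
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, index=False)


def read_events_csv(path):
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy()
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return times, labels


# --------------------------------------------------------------------------- #
# truth sidecars

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, StateSchedule):
        return {"__schedule__": obj.intervals}
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(path, truth: SyntheticTruth) -> None:
    payload = {
        "bout_starts_s": _jsonable(truth.bout_starts_s),
        "bout_durations_s": _jsonable(truth.bout_durations_s),
        "flash_times_s": _jsonable(truth.flash_times_s),
        "state_schedule": _jsonable(truth.state_schedule),
        "params": _jsonable(truth.params),
        "events": _jsonable(truth.events),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    sched = payload.get("state_schedule")
    if isinstance(sched, dict) and "__schedule__" in sched:
        sched = StateSchedule([tuple(iv) for iv in sched["__schedule__"]])
    return SyntheticTruth(
        bout_starts_s=np.asarray(payload.get("bout_starts_s", [])),
        bout_durations_s=np.asarray(payload.get("bout_durations_s", [])),
        flash_times_s=np.asarray(payload.get("flash_times_s", [])),
        state_schedule=sched,
        params=payload.get("params", {}),
        events=payload.get("events", {}),
    )


# --------------------------------------------------------------------------- #
# pattern features

def write_features_h5(path, trajectories) -> None:
    with h5py.File(path, "w") as f:
        for k, tr in enumerate(trajectories):
            d = f.create_dataset(f"features/{k:04d}", data=tr.features)
            d.attrs["fps"] = tr.fps
            d.attrs["animal"] = tr.animal_id
            d.attrs["bout"] = tr.bout_id


def read_features_h5(path) -> list[PatternTrajectory]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["features"]):
            d = f[f"features/{key}"]
            out.append(PatternTrajectory(
                d[()], fps=float(d.attrs["fps"]),
                animal_id=str(d.attrs.get("animal", "")),
                bout_id=str(d.attrs.get("bout", "")),
            ))
    return out
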