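"""Core data containers shared across the behaviour, ephys and pattern modules.

Conventions
-----------
* All event times and interval bounds are **seconds from trace start**;
  frames are 0-based and converted with the exact frame rate, never rounded
  rates.
* Brightness is in 8-bit camera units (0-255); LFP is in microvolts.
* Skin darkening is a brightness *decrease*: the resting pattern is uniform
  white, so active-sleep bouts and quiet-sleep colour flashes appear as
  negative brightness excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BrightnessTrace",
    "MovementTrace",
    "StateSchedule",
    "LFPRecording",
    "PatternTrajectory",
    "SyntheticTruth",
]


def _as_1d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D trace, got shape {arr.shape}")
    return arr


@dataclass
class BrightnessTrace:
    """Per-frame mean skin brightness.

    Parameters
    ----------
    values : array of brightness units (0-255), one sample per frame.
    fps : frame rate in frames per second.
    t0 : time of the first frame, seconds.
    """

    values: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = _as_1d_float(self.values)
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.values.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fps

    def index_of(self, t_s: float) -> int:
        """Nearest frame index for a time in seconds."""
        return int(round((t_s - self.t0) * self.fps))


@dataclass
class MovementTrace:
    """Non-negative movement-magnitude trace (mean optic-flow magnitude)."""

    values: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = _as_1d_float(self.values)
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps


@dataclass
class StateSchedule:
    """Labelled behavioural intervals (e.g. ``AS``, ``QS``, ``wake``) in seconds.

    Intervals are ``(label, start_s, end_s)`` with ``start_s < end_s``.
    Intervals sharing a label must not overlap.
    """

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        clean = []
        for label, s, e in self.intervals:
            s, e = float(s), float(e)
            if not e > s:
                raise ValueError(f"interval {label!r} has end {e} <= start {s}")
            clean.append((str(label), s, e))
        self.intervals = sorted(clean, key=lambda iv: iv[1])
        for label in self.labels():
            ivs = self.by_label(label)
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {label!r} intervals at {s1:.3f} s")

    def labels(self) -> list[str]:
        return sorted({label for label, _, _ in self.intervals})

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.intervals if lab == label]

    def onsets(self, label: str) -> np.ndarray:
        return np.array([s for lab, s, _ in self.intervals if lab == label])

    @property
    def end_s(self) -> float:
        return max((e for _, _, e in self.intervals), default=0.0)

    def coverage_gaps(self, duration_s: float, tol: float = 1e-9) -> list[tuple[float, float]]:
        """Sub-intervals of ``[0, duration_s]`` covered by no labelled interval."""
        gaps = []
        cursor = 0.0
        for _, s, e in self.intervals:
            if s > cursor + tol:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor + tol < duration_s:
            gaps.append((cursor, duration_s))
        return gaps

    def state_at(self, t_s: float) -> str | None:
        for label, s, e in self.intervals:
            if s <= t_s < e:
                return label
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["label", "start_s", "end_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StateSchedule":
        return cls([(r.label, r.start_s, r.end_s) for r in df.itertuples()])


#: columns every channel table must carry
CHANNEL_COLUMNS = ("x_um", "y_um", "z_um", "region", "in_brain")


@dataclass
class LFPRecording:
    """Multi-channel LFP with per-channel atlas coordinates and region labels.

    Parameters
    ----------
    data : (n_channels, n_samples) array, microvolts.
    fs_Hz : sampling rate, samples per second.
    channels : table with columns ``x_um, y_um, z_um, region, in_brain`` and
        optionally ``probe`` (probe identity, needed for region aggregation).
    """

    data: np.ndarray
    fs_Hz: float
    channels: pd.DataFrame

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if not self.fs_Hz > 0:
            raise ValueError("fs_Hz must be positive")
        missing = [c for c in CHANNEL_COLUMNS if c not in self.channels.columns]
        if missing:
            raise ValueError(f"channel table missing columns: {missing}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel table length does not match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("LFP data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_Hz

    def out_of_brain_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.channels["in_brain"].to_numpy(bool))

    def in_brain_indices(self) -> np.ndarray:
        return np.flatnonzero(self.channels["in_brain"].to_numpy(bool))


@dataclass
class PatternTrajectory:
    """T x D matrix of per-frame skin-pattern feature vectors for one bout."""

    features: np.ndarray
    fps: float
    animal_id: str = ""
    bout_id: str = ""

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.features.shape[0] < 2:
            raise ValueError("trajectory needs at least two frames")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset.

    The behaviour generator fills ``bout_starts_s``/``bout_durations_s``/
    ``flash_times_s``; other generators use ``events`` for their own logs
    (spindle times, visited pattern sequences, breath peaks, ...).  ``params``
    records the generating configuration as a plain dict.
    """

    bout_starts_s: np.ndarray = field(default_factory=lambda: np.array([]))
    bout_durations_s: np.ndarray = field(default_factory=lambda: np.array([]))
    flash_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    state_schedule: StateSchedule | None = None
    params: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
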