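"""Core data types and CSV I/O shared by all processing stages.

An :class:`IMURecording` holds a uniformly sampled six-channel inertial
time series (tri-axial accelerometer in m/s², tri-axial gyroscope in
rad/s) with optional per-sample activity labels.  A :class:`Segment` is a
half-open index window ``[start, end)`` into a recording.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMURecording",
    "Segment",
    "FormatError",
    "SamplingError",
    "CHANNEL_NAMES",
    "ACTIVITY_LABELS",
    "read_imu_csv",
    "write_imu_csv",
    "write_events_csv",
    "read_events_csv",
]

#: Accelerometer then gyroscope axis names, in storage order.
CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

#: Recognized per-sample activity tags.
ACTIVITY_LABELS = ("WK", "SA", "SD", "RUN", "STAND", "OTHER")

_TIME_TOL_S = 1e-9


class FormatError(ValueError):
    """Raised when a CSV file does not match the expected layout."""


class SamplingError(ValueError):
    """Raised when timestamps are not uniform at the declared rate."""

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class IMURecording:
    """Uniformly sampled six-channel inertial recording.

    Parameters
    ----------
    time : ndarray
        Sample timestamps in seconds, monotone with uniform step ``1/fs``.
    ax, ay, az : ndarray
        Acceleration channels, m/s².
    gx, gy, gz : ndarray
        Angular-velocity channels, rad/s; ``gz`` is the sagittal plane.
    fs : float
        Sampling rate in Hz (default 100).
    labels : ndarray of str, optional
        Per-sample activity tags; empty array when absent.
    subject_id : str
        Opaque subject identifier.
    """

    time: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    fs: float = 100.0
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    subject_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        for name in CHANNEL_NAMES:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        n = len(self.time)
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in CHANNEL_NAMES:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length {len(getattr(self, name))} != {n}")
        if self.labels.size and len(self.labels) != n:
            raise ValueError("labels length must match channels")
        steps = np.diff(self.time)
        bad = np.nonzero(np.abs(steps - 1.0 / self.fs) > _TIME_TOL_S)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise SamplingError(
                f"non-uniform time step at index {i}: got {steps[bad[0]]!r}, "
                f"expected {1.0 / self.fs!r}",
                index=i,
            )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def has_labels(self) -> bool:
        return self.labels.size > 0

    def channels(self) -> dict[str, np.ndarray]:
        """Channel name → array view, in storage order."""
        return {name: getattr(self, name) for name in CHANNEL_NAMES}

    def replace(self, **changes) -> "IMURecording":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Segment:
    """Half-open index window ``[start_index, end_index)`` of a recording."""

    recording: IMURecording
    start_index: int
    end_index: int
    activity_label: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start_index < self.end_index <= len(self.recording)):
            raise ValueError(
                f"invalid segment bounds [{self.start_index}, {self.end_index}) "
                f"for recording of length {len(self.recording)}"
            )

    def __len__(self) -> int:
        return self.end_index - self.start_index

    def channel(self, name: str) -> np.ndarray:
        """Slice of a single channel, never reaching outside the window."""
        return getattr(self.recording, name)[self.start_index : self.end_index]

    def channels(self) -> dict[str, np.ndarray]:
        return {name: self.channel(name) for name in CHANNEL_NAMES}

    @property
    def labels(self) -> np.ndarray:
        if not self.recording.has_labels:
            return np.empty(0, dtype=object)
        return self.recording.labels[self.start_index : self.end_index]


_REQUIRED_COLUMNS = ("time_s",) + CHANNEL_NAMES


def read_imu_csv(path, subject_id: str = "") -> IMURecording:
    """Read an IMU recording from CSV.

    Expected header ``time_s,ax,ay,az,gx,gy,gz[,label]``; lines starting
    with ``#`` are comments.  A ``# sampling_rate_hz: <value>`` comment
    pins the sampling rate, otherwise it is inferred from the median time
    step; a mismatch beyond 0.1% raises :class:`SamplingError`.
    """
    path = Path(path)
    declared_fs = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("sampling_rate_hz:"):
                declared_fs = float(stripped.split(":", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) > 1:
        steps = np.diff(time)
        median_step = float(np.median(steps))
        if median_step <= 0:
            raise SamplingError("non-increasing timestamps", index=1)
        fs = 1.0 / median_step
        if declared_fs is not None:
            if abs(fs - declared_fs) / declared_fs > 1e-3:
                raise SamplingError(
                    f"declared sampling rate {declared_fs} Hz disagrees with "
                    f"inferred {fs:.6g} Hz by more than 0.1%",
                    index=0,
                )
            fs = declared_fs
        bad = np.nonzero(np.abs(steps - 1.0 / fs) > max(_TIME_TOL_S, 1e-6 / fs))[0]
        if bad.size == steps.size and declared_fs is None:
            # median step itself corrupted (e.g. 2-step file): anchor on
            # the first step so the first offending row is reported
            fs = 1.0 / steps[0]
            bad = np.nonzero(np.abs(steps - steps[0]) > max(_TIME_TOL_S, 1e-6 / fs))[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise SamplingError(f"non-uniform time step at index {i}", index=i)
    else:
        fs = declared_fs if declared_fs is not None else 100.0
    labels = (
        df["label"].astype(object).to_numpy()
        if "label" in df.columns
        else np.empty(0, dtype=object)
    )
    kwargs = {name: df[name].to_numpy(dtype=float) for name in CHANNEL_NAMES}
    return IMURecording(
        time=time, fs=fs, labels=labels, subject_id=subject_id, **kwargs
    )


def write_imu_csv(recording: IMURecording, path) -> None:
    """Write a recording to CSV with ≥ 9 significant digits per value."""
    path = Path(path)
    data = {"time_s": recording.time}
    data.update(recording.channels())
    df = pd.DataFrame(data)
    if recording.has_labels:
        df["label"] = recording.labels
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# sampling_rate_hz: {recording.fs!r}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def write_events_csv(events: Sequence, path) -> None:
    """Write gait events as ``event_type,time_s,sample_index,value_rad_s``.

    Events must be time-ordered; the write/read round trip reproduces the
    sequence exactly.
    """
    for prev, cur in zip(events, events[1:]):
        if cur.sample_index < prev.sample_index:
            raise ValueError(
                f"events out of order at sample_index {cur.sample_index} "
                f"after {prev.sample_index}"
            )
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("event_type,time_s,sample_index,value_rad_s\n")
        for ev in events:
            fh.write(f"{ev.event_type},{ev.time_s!r},{ev.sample_index},{ev.value!r}\n")


def read_events_csv(path) -> list:
    """Read back an events CSV written by :func:`write_events_csv`."""
    from .gait_segmentation import GaitEvent  # deferred: avoid cycle at import

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("event_type", "time_s", "sample_index", "value_rad_s"):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col}")
    return [
        GaitEvent(
            event_type=str(row.event_type),
            sample_index=int(row.sample_index),
            time_s=float(row.time_s),
            value=float(row.value_rad_s),
        )
        for row in df.itertuples()
    ]
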