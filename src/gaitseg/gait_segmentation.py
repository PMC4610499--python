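"""Streaming rule-based gait-cycle detection from sagittal angular velocity.

The detector walks the g_z channel one sample at a time with constant
memory (no lookback or lookahead windows) through three phases:

* ``SEEKING_SWING`` — track a rising zero crossing and the running
  maximum of the positive lobe; at the falling crossing, if the maximum
  exceeds the swing threshold, the argmax is emitted as ``MID_SWING``.
* ``SEEKING_FOOT_STRIKE`` — the first confirmed local minimum after the
  falling crossing is emitted as ``FOOT_STRIKE`` (t_fs).
* ``SEEKING_FOOT_OFF`` — maintain the latest confirmed local maximum
  (t_max) and subsequent local minimum (t_min); when
  ``t_min − t_max ≥ 60 ms  and  g_z(t_min) ≤ 1.4 rad/s  and
  t_max − t_fs ≥ 70 ms`` holds, ``FOOT_OFF`` is emitted at t_min.  If the
  condition is not met within the timeout after the swing was confirmed,
  the pending swing is discarded.

A gait cycle is the half-open sample window between two consecutive
``FOOT_OFF`` events.  Local extrema are confirmed one sample after the
trend reversal; plateaus take the first plateau sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .signal_model import IMURecording, Segment

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "GaitEvent",
    "GaitCycle",
    "MID_SWING",
    "FOOT_STRIKE",
    "FOOT_OFF",
    "step_detector",
    "detect_events",
    "cycles_from_events",
    "initial_state",
]

MID_SWING = "MID_SWING"
FOOT_STRIKE = "FOOT_STRIKE"
FOOT_OFF = "FOOT_OFF"

SEEKING_SWING = "SEEKING_SWING"
SEEKING_FOOT_STRIKE = "SEEKING_FOOT_STRIKE"
SEEKING_FOOT_OFF = "SEEKING_FOOT_OFF"


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the rule-based detector.

    Defaults implement the published rules: swing peak above 1.8 rad/s,
    foot-off value at most 1.4 rad/s, minimum gaps of 60 ms (t_min−t_max)
    and 70 ms (t_max−t_fs), and a 1.3 s timeout.
    """

    swing_peak_threshold: float = 1.8
    footoff_value_threshold: float = 1.4
    min_tmin_tmax_gap: float = 0.060
    min_tmax_tfs_gap: float = 0.070
    timeout: float = 1.3
    fs: float = 100.0

    def __post_init__(self):
        for name in ("swing_peak_threshold", "footoff_value_threshold",
                     "min_tmin_tmax_gap", "min_tmax_tfs_gap", "timeout", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.timeout <= max(self.min_tmin_tmax_gap, self.min_tmax_tfs_gap):
            raise ValueError("timeout must exceed the minimum gaps")


@dataclass(frozen=True)
class GaitEvent:
    """A detected gait event located at a single sample."""

    event_type: str
    sample_index: int
    time_s: float
    value: float

    def __post_init__(self):
        if self.event_type not in (MID_SWING, FOOT_STRIKE, FOOT_OFF):
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class DetectorState:
    """Constant-size memory of the streaming automaton."""

    phase: str = SEEKING_SWING
    next_index: int = 0
    prev_value: float = math.nan
    last_dir: int = 0          # sign of the last nonzero sample-to-sample change
    turn_index: int = -1       # last sample of the current monotone run
    turn_value: float = math.nan
    in_positive_lobe: bool = False
    run_max_index: int = -1
    run_max_value: float = -math.inf
    swing_confirm_index: int = -1   # falling crossing that confirmed the swing
    mid_swing_index: int = -1
    foot_strike_index: int = -1
    tmax_index: int = -1
    tmax_value: float = math.nan
    tmin_index: int = -1
    tmin_value: float = math.nan


def initial_state() -> DetectorState:
    return DetectorState()


def _reset_to_seeking(state: DetectorState) -> DetectorState:
    return replace(
        state,
        phase=SEEKING_SWING,
        in_positive_lobe=False,
        run_max_index=-1,
        run_max_value=-math.inf,
        swing_confirm_index=-1,
        mid_swing_index=-1,
        foot_strike_index=-1,
        tmax_index=-1,
        tmax_value=math.nan,
        tmin_index=-1,
        tmin_value=math.nan,
    )


def _event(event_type: str, index: int, value: float, fs: float) -> GaitEvent:
    return GaitEvent(event_type=event_type, sample_index=index,
                     time_s=index / fs, value=value)


def step_detector(
    state: DetectorState,
    sample: tuple[int, float],
    config: DetectorConfig,
) -> tuple[DetectorState, list[GaitEvent]]:
    """Advance the automaton by one sample; return new state and emissions.

    Samples must arrive in index order with no gaps.  Processing a
    sequence whole or chunked with carried state yields identical events.
    """
    index, value = sample
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite g_z sample at index {index}")
    if index != state.next_index:
        raise ValueError(
            f"out-of-order sample index {index}; expected {state.next_index}"
        )

    events: list[GaitEvent] = []
    s = {f: getattr(state, f) for f in DetectorState.__dataclass_fields__}
    s["next_index"] = index + 1

    prev = state.prev_value
    s["prev_value"] = value

    if index == 0 or not math.isfinite(prev):
        s["turn_index"] = index
        s["turn_value"] = value
        return DetectorState(**s), events

    # -- local-extremum confirmation (one sample of latency) -------------
    d = 0
    if value > prev:
        d = 1
    elif value < prev:
        d = -1
    confirmed_min: Optional[tuple[int, float]] = None
    confirmed_max: Optional[tuple[int, float]] = None
    if d > 0:
        if s["last_dir"] < 0:
            confirmed_min = (s["turn_index"], s["turn_value"])
        s["last_dir"] = 1
    elif d < 0:
        if s["last_dir"] > 0:
            confirmed_max = (s["turn_index"], s["turn_value"])
        s["last_dir"] = -1
    if d != 0:
        s["turn_index"] = index
        s["turn_value"] = value
    # plateau: turn_index stays at the first plateau sample

    rising = prev < 0.0 <= value
    falling = prev >= 0.0 > value

    # -- timeout: discard the pending swing ------------------------------
    if s["phase"] != SEEKING_SWING:
        elapsed = (index - s["swing_confirm_index"]) / config.fs
        if elapsed > config.timeout:
            tmp = _reset_to_seeking(DetectorState(**s))
            s = {f: getattr(tmp, f) for f in DetectorState.__dataclass_fields__}

    if s["phase"] == SEEKING_SWING:
        if rising:
            s["in_positive_lobe"] = True
            s["run_max_index"] = index
            s["run_max_value"] = value
        elif s["in_positive_lobe"] and value > s["run_max_value"]:
            s["run_max_index"] = index
            s["run_max_value"] = value
        if falling and s["in_positive_lobe"]:
            if s["run_max_value"] > config.swing_peak_threshold:
                events.append(
                    _event(MID_SWING, s["run_max_index"], s["run_max_value"], config.fs)
                )
                s["phase"] = SEEKING_FOOT_STRIKE
                s["swing_confirm_index"] = index
                s["mid_swing_index"] = s["run_max_index"]
                s["foot_strike_index"] = -1
                s["tmax_index"] = -1
                s["tmin_index"] = -1
            s["in_positive_lobe"] = False
            s["run_max_index"] = -1
            s["run_max_value"] = -math.inf

    elif s["phase"] == SEEKING_FOOT_STRIKE:
        if confirmed_min is not None:
            j, v = confirmed_min
            events.append(_event(FOOT_STRIKE, j, v, config.fs))
            s["phase"] = SEEKING_FOOT_OFF
            s["foot_strike_index"] = j
            s["tmax_index"] = -1
            s["tmin_index"] = -1

    elif s["phase"] == SEEKING_FOOT_OFF:
        if confirmed_max is not None:
            s["tmax_index"], s["tmax_value"] = confirmed_max
            s["tmin_index"] = -1
        if confirmed_min is not None and s["tmax_index"] >= 0:
            s["tmin_index"], s["tmin_value"] = confirmed_min
            gap_mm = (s["tmin_index"] - s["tmax_index"]) / config.fs
            gap_mf = (s["tmax_index"] - s["foot_strike_index"]) / config.fs
            eps = 1e-12
            if (
                gap_mm >= config.min_tmin_tmax_gap - eps
                and s["tmin_value"] <= config.footoff_value_threshold
                and gap_mf >= config.min_tmax_tfs_gap - eps
            ):
                events.append(
                    _event(FOOT_OFF, s["tmin_index"], s["tmin_value"], config.fs)
                )
                tmp = _reset_to_seeking(DetectorState(**s))
                s = {f: getattr(tmp, f) for f in DetectorState.__dataclass_fields__}
                if rising:  # crossing on the confirmation sample itself
                    s["in_positive_lobe"] = True
                    s["run_max_index"] = index
                    s["run_max_value"] = value

    return DetectorState(**s), events


def detect_events(
    gz: Iterable[float],
    config: Optional[DetectorConfig] = None,
) -> list[GaitEvent]:
    """Run the streaming detector over a whole g_z sequence."""
    if config is None:
        config = DetectorConfig()
    state = initial_state()
    events: list[GaitEvent] = []
    for i, value in enumerate(gz):
        state, emitted = step_detector(state, (i, float(value)), config)
        events.extend(emitted)
    return events


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle delimited by two consecutive foot-off events."""

    start: GaitEvent
    end: GaitEvent
    segment: Segment
    activity_label: Optional[str] = None

    def __post_init__(self):
        if self.end.sample_index <= self.start.sample_index:
            raise ValueError("cycle end must follow its start")


def _majority_label(labels: np.ndarray) -> Optional[str]:
    # Majority per-sample label; ties broken toward the label whose run
    # starts earliest in the window.
    if labels.size == 0:
        return None
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        lab = str(lab)
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    best = max(counts.items(), key=lambda kv: (kv[1], -first_seen[kv[0]]))
    return best[0]


def cycles_from_events(
    events: Iterable[GaitEvent],
    recording: IMURecording,
) -> list[GaitCycle]:
    """Assemble cycles from adjacent FOOT_OFF pairs; other events only
    delimit nothing.  Consecutive cycles share their boundary event."""
    foot_offs = [e for e in events if e.event_type == FOOT_OFF]
    for prev, cur in zip(foot_offs, foot_offs[1:]):
        if cur.sample_index <= prev.sample_index:
            raise ValueError("foot-off events out of order")
    cycles: list[GaitCycle] = []
    for start, end in zip(foot_offs, foot_offs[1:]):
        label = None
        if recording.has_labels:
            label = _majority_label(
                recording.labels[start.sample_index : end.sample_index]
            )
        segment = Segment(recording, start.sample_index, end.sample_index,
                          activity_label=label)
        cycles.append(GaitCycle(start=start, end=end, segment=segment,
                                activity_label=label))
    return cycles
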