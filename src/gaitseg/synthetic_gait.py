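"""Synthetic labeled shank-IMU sessions with exact gait-event annotations.

The sagittal angular-velocity channel of each stride is a chain of
half-cosine arcs through five keypoints — opening foot-off minimum,
swing-phase maximum (mid-swing), foot-strike minimum, a small positive
stance bump, and the closing foot-off minimum — so every annotated event
is an analytic extremum of the template.  Activity blocks are separated
by standing rests; acceleration channels are activity-scaled periodic
waveforms.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .signal_model import IMURecording

__all__ = [
    "ActivityProfile",
    "CycleAnnotation",
    "SyntheticAnnotation",
    "DEFAULT_PROFILES",
    "DEFAULT_PROTOCOL",
    "generate_cycle",
    "generate_session",
    "generate_cohort",
]

#: Within-cycle event positions as fractions of the cycle duration.
_MID_SWING_FRAC = 0.25
_FOOT_STRIKE_FRAC = 0.42
#: Fixed duration of the steep pre-swing drop into the foot-off minimum.
#: Kept short so its slope dwarfs the sample noise: gentle descending
#: slopes below the foot-off value threshold would let noise-confirmed
#: extremum pairs satisfy the foot-off rule early.
_PRESWING_DROP_S = 0.105

_MIN_CYCLE_S = 0.45
_TAIL_S = 0.15  # recovery from the last foot-off minimum back to baseline


@dataclass(frozen=True)
class ActivityProfile:
    """Stochastic template parameters for one activity."""

    activity: str
    cycle_duration_mean: float
    cycle_duration_sd: float
    swing_peak_mean: float
    swing_peak_sd: float
    foot_strike_depth: float     # magnitude of the negative foot-strike lobe
    foot_off_depth: float        # magnitude of the negative foot-off lobe
    accel_amplitudes: tuple[float, float, float] = (2.0, 3.0, 1.2)
    stance_bump: float = 0.5
    noise_sd_gyro: float = 0.08
    noise_sd_accel: float = 0.25

    def __post_init__(self):
        if self.activity not in ("WK", "SA", "SD", "RUN"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.cycle_duration_mean <= 0.4:
            raise ValueError("cycle_duration_mean must exceed 0.4 s")
        if self.swing_peak_mean < 3.0:
            raise ValueError("swing_peak_mean must be at least 3.0 rad/s")
        if self.swing_peak_mean - 1.8 < 3 * self.noise_sd_gyro:
            raise ValueError("swing peak must clear 1.8 rad/s by 3 noise sd")
        for name in ("foot_strike_depth", "foot_off_depth", "stance_bump"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_PROFILES: dict[str, ActivityProfile] = {
    "WK": ActivityProfile("WK", 1.10, 0.06, 4.5, 0.25, 2.0, 2.8,
                          accel_amplitudes=(2.0, 3.0, 1.2)),
    "SA": ActivityProfile("SA", 1.40, 0.08, 3.5, 0.20, 2.4, 2.8,
                          accel_amplitudes=(1.4, 2.2, 1.0)),
    "SD": ActivityProfile("SD", 1.20, 0.07, 4.0, 0.22, 2.4, 2.8,
                          accel_amplitudes=(1.8, 2.6, 1.6)),
    "RUN": ActivityProfile("RUN", 0.75, 0.04, 7.0, 0.35, 3.5, 3.2,
                           accel_amplitudes=(5.0, 8.0, 3.0)),
}

#: Session protocol mirroring one route: walking, stairs up, walking,
#: running, stairs down, walking — with standing rests in between.
DEFAULT_PROTOCOL: tuple[tuple[str, int], ...] = (
    ("WK", 20), ("SA", 15), ("WK", 10), ("RUN", 20), ("SD", 15), ("WK", 10),
)


@dataclass(frozen=True)
class CycleAnnotation:
    """Ground-truth event times (absolute seconds) for one gait cycle."""

    activity: str
    start_foot_off_s: float
    mid_swing_s: float
    foot_strike_s: float
    end_foot_off_s: float

    def __post_init__(self):
        times = (self.start_foot_off_s, self.mid_swing_s,
                 self.foot_strike_s, self.end_foot_off_s)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("cycle event times must be strictly increasing")


@dataclass(frozen=True)
class SyntheticAnnotation:
    """Ground truth emitted alongside a generated recording."""

    cycles: tuple[CycleAnnotation, ...]
    subject_id: str = ""
    bias: tuple[float, ...] = (0.0,) * 6
    seed: Optional[int] = None

    def foot_off_times(self) -> np.ndarray:
        """All annotated foot-off instants (cycle boundaries), sorted."""
        times = set()
        for c in self.cycles:
            times.add(c.start_foot_off_s)
            times.add(c.end_foot_off_s)
        return np.array(sorted(times))


def _cosine_chain(kp_t: np.ndarray, kp_v: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Evaluate a chain of half-cosine arcs through keypoints at times ts."""
    idx = np.clip(np.searchsorted(kp_t, ts, side="right") - 1, 0, len(kp_t) - 2)
    ta, tb = kp_t[idx], kp_t[idx + 1]
    va, vb = kp_v[idx], kp_v[idx + 1]
    u = np.clip((ts - ta) / (tb - ta), 0.0, 1.0)
    return va + (vb - va) * (1.0 - np.cos(np.pi * u)) / 2.0


def _stride_keypoints(t0: float, duration: float, peak: float,
                      profile: ActivityProfile, opening_value: float):
    """Keypoints of one stride starting at t0 with the given opening value.

    A lead-in stride (opening at baseline 0) gets a small negative
    pre-swing dip so the rising zero crossing survives small positive
    baseline bias.
    """
    head: list[tuple[float, float]] = [(t0, opening_value)]
    if opening_value == 0.0:
        head.append((t0 + 0.08 * duration, -0.35))
    return head + [
        (t0 + _MID_SWING_FRAC * duration, peak),
        (t0 + _FOOT_STRIKE_FRAC * duration, -profile.foot_strike_depth),
        (t0 + duration - _PRESWING_DROP_S, profile.stance_bump),
        (t0 + duration, -profile.foot_off_depth),
    ]


def _draw_stride(profile: ActivityProfile, rng: np.random.Generator):
    duration = max(_MIN_CYCLE_S,
                   rng.normal(profile.cycle_duration_mean, profile.cycle_duration_sd))
    floor = 1.8 + 3 * profile.noise_sd_gyro + 0.3
    peak = max(floor, rng.normal(profile.swing_peak_mean, profile.swing_peak_sd))
    return duration, peak


def _accel_waveforms(phase: np.ndarray, active: np.ndarray,
                     profile: ActivityProfile) -> dict[str, np.ndarray]:
    Aax, Aay, Aaz = profile.accel_amplitudes
    P = profile.swing_peak_mean
    two_pi = 2.0 * np.pi * phase
    out = {
        "ax": Aax * np.sin(two_pi + 0.5),
        "ay": Aay * np.cos(two_pi),
        "az": Aaz * np.sin(2 * two_pi + 1.0),
        "gx": 0.12 * P * np.sin(two_pi + 1.0),
        "gy": 0.10 * P * np.cos(2 * two_pi),
    }
    for k in out:
        out[k] = np.where(active, out[k], 0.0)
    return out


def generate_cycle(
    profile: ActivityProfile,
    rng: np.random.Generator,
    fs: float = 100.0,
) -> tuple[dict[str, np.ndarray], CycleAnnotation]:
    """Generate one standalone gait cycle plus a short recovery tail.

    Returns the six sampled channels and the exact event annotation.
    The cycle starts at the opening foot-off minimum (t = 0).
    """
    if not isinstance(rng, np.random.Generator):
        raise ValueError("an explicit numpy Generator is required")
    duration, peak = _draw_stride(profile, rng)
    kp = _stride_keypoints(0.0, duration, peak, profile, -profile.foot_off_depth)
    kp.append((duration + _TAIL_S, 0.0))
    kp_t = np.array([t for t, _ in kp])
    kp_v = np.array([v for _, v in kp])
    n = int(round((duration + _TAIL_S) * fs)) + 1
    ts = np.arange(n) / fs
    gz = _cosine_chain(kp_t, kp_v, ts)
    phase = np.clip(ts / duration, 0.0, 1.0)
    active = ts <= duration
    waves = _accel_waveforms(phase, active, profile)
    channels = {name: waves[name] for name in ("ax", "ay", "az", "gx", "gy")}
    channels["gz"] = gz
    for name in ("ax", "ay", "az"):
        channels[name] = channels[name] + rng.normal(0, profile.noise_sd_accel, n)
    for name in ("gx", "gy", "gz"):
        channels[name] = channels[name] + rng.normal(0, profile.noise_sd_gyro, n)
    annotation = CycleAnnotation(
        activity=profile.activity,
        start_foot_off_s=0.0,
        mid_swing_s=_MID_SWING_FRAC * duration,
        foot_strike_s=_FOOT_STRIKE_FRAC * duration,
        end_foot_off_s=duration,
    )
    return channels, annotation


def generate_session(
    protocol: Sequence[tuple[str, int]] = DEFAULT_PROTOCOL,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    profiles: Optional[dict[str, ActivityProfile]] = None,
    subject_id: str = "S0",
    bias: Optional[Sequence[float]] = None,
    fs: float = 100.0,
    lead_standing_s: float = 5.0,
    rest_s: float = 2.5,
) -> tuple[IMURecording, SyntheticAnnotation]:
    """Generate a full labeled session.

    The session opens with ``lead_standing_s`` seconds of standing (for
    offset initialization), then runs the protocol's activity blocks
    separated by standing rests.  Each block carries one unannotated
    lead-in stride (its closing foot-off opens the first annotated
    cycle) followed by ``n_cycles`` annotated cycles and a short return
    to baseline.  ``bias`` is a constant per-channel additive vector
    emulating sensor inclination.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    profiles = dict(DEFAULT_PROFILES, **(profiles or {}))
    bias_vec = tuple(float(v) for v in (bias if bias is not None else (0.0,) * 6))
    if len(bias_vec) != 6:
        raise ValueError("bias must have six components")

    chunks: dict[str, list[np.ndarray]] = {k: [] for k in
                                           ("ax", "ay", "az", "gx", "gy", "gz")}
    label_chunks: list[np.ndarray] = []
    cycles: list[CycleAnnotation] = []
    i0 = 0  # global sample counter

    def append_standing(duration_s: float):
        nonlocal i0
        n = int(round(duration_s * fs))
        for name in ("ax", "ay", "az"):
            prof = profiles["WK"]
            chunks[name].append(rng.normal(0, prof.noise_sd_accel, n))
        for name in ("gx", "gy", "gz"):
            prof = profiles["WK"]
            chunks[name].append(rng.normal(0, prof.noise_sd_gyro, n))
        label_chunks.append(np.full(n, "STAND", dtype=object))
        i0 += n

    def append_block(activity: str, n_cycles: int):
        nonlocal i0
        profile = profiles[activity]
        block_start = i0 / fs
        # lead-in stride from baseline plus n_cycles annotated cycles
        kp: list[tuple[float, float]] = []
        t = 0.0
        durations = []
        for j in range(n_cycles + 1):
            duration, peak = _draw_stride(profile, rng)
            opening = 0.0 if j == 0 else -profile.foot_off_depth
            stride = _stride_keypoints(t, duration, peak, profile, opening)
            if j > 0:
                stride = stride[1:]  # boundary keypoint shared with previous
            kp.extend(stride)
            durations.append(duration)
            t += duration
        total_active = t
        kp.append((t + _TAIL_S, 0.0))
        kp_t = np.array([p[0] for p in kp])
        kp_v = np.array([p[1] for p in kp])
        n = int(round((total_active + _TAIL_S) * fs))
        ts = np.arange(n) / fs
        gz = _cosine_chain(kp_t, kp_v, ts)
        starts = np.concatenate([[0.0], np.cumsum(durations)])
        idx = np.clip(np.searchsorted(starts, ts, side="right") - 1,
                      0, len(durations) - 1)
        phase = (ts - starts[idx]) / np.asarray(durations)[idx]
        active = ts <= total_active
        waves = _accel_waveforms(np.clip(phase, 0.0, 1.0), active, profile)
        for name in ("ax", "ay", "az"):
            chunks[name].append(waves[name] + rng.normal(0, profile.noise_sd_accel, n))
        for name in ("gx", "gy"):
            chunks[name].append(waves[name] + rng.normal(0, profile.noise_sd_gyro, n))
        chunks["gz"].append(gz + rng.normal(0, profile.noise_sd_gyro, n))
        label_chunks.append(np.full(n, activity, dtype=object))
        # annotations: cycle j spans foot-off j-1 → foot-off j (1-based strides)
        for j in range(1, n_cycles + 1):
            t_start = block_start + starts[j]
            duration = durations[j]
            cycles.append(CycleAnnotation(
                activity=activity,
                start_foot_off_s=t_start,
                mid_swing_s=t_start + _MID_SWING_FRAC * duration,
                foot_strike_s=t_start + _FOOT_STRIKE_FRAC * duration,
                end_foot_off_s=t_start + duration,
            ))
        i0 += n

    append_standing(lead_standing_s)
    for k, (activity, n_cycles) in enumerate(protocol):
        if k > 0:
            append_standing(rest_s)
        append_block(activity, int(n_cycles))
    append_standing(rest_s)

    data = {name: np.concatenate(chunks[name]) for name in chunks}
    for name, b in zip(("ax", "ay", "az", "gx", "gy", "gz"), bias_vec):
        data[name] = data[name] + b
    n_total = len(data["gz"])
    recording = IMURecording(
        time=np.arange(n_total) / fs,
        fs=fs,
        labels=np.concatenate(label_chunks),
        subject_id=subject_id,
        **data,
    )
    annotation = SyntheticAnnotation(
        cycles=tuple(cycles), subject_id=subject_id, bias=bias_vec, seed=seed
    )
    return recording, annotation


def _jitter_profiles(
    profiles: dict[str, ActivityProfile],
    rng: np.random.Generator,
    scale: float,
) -> dict[str, ActivityProfile]:
    out = {}
    for name, p in profiles.items():
        out[name] = replace(
            p,
            cycle_duration_mean=p.cycle_duration_mean
            * float(np.clip(rng.normal(1.0, 0.04 * scale), 0.88, 1.12)),
            swing_peak_mean=max(
                3.0, p.swing_peak_mean
                * float(np.clip(rng.normal(1.0, 0.05 * scale), 0.85, 1.15))
            ),
            accel_amplitudes=tuple(
                a * float(np.clip(rng.normal(1.0, 0.05 * scale), 0.8, 1.2))
                for a in p.accel_amplitudes
            ),
        )
    return out


def generate_cohort(
    n_subjects: int,
    protocol: Sequence[tuple[str, int]] = DEFAULT_PROTOCOL,
    seed: Optional[int] = None,
    profiles: Optional[dict[str, ActivityProfile]] = None,
    variability_scale: float = 1.0,
    with_bias: bool = True,
    fs: float = 100.0,
) -> list[tuple[IMURecording, SyntheticAnnotation]]:
    """Generate a cohort with per-subject profile jitter.

    Each subject draws from a distinct sub-seed of ``seed``; the whole
    cohort is deterministic for a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    base = dict(DEFAULT_PROFILES, **(profiles or {}))
    sub_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for k, ss in enumerate(sub_seeds):
        rng = np.random.default_rng(ss)
        subject_profiles = _jitter_profiles(base, rng, variability_scale)
        if with_bias:
            bias = (
                rng.normal(0.0, 0.3), rng.normal(0.0, 0.3),
                9.81 + rng.normal(0.0, 0.2),
                rng.normal(0.0, 0.015), rng.normal(0.0, 0.015),
                rng.normal(0.0, 0.015),
            )
        else:
            bias = (0.0,) * 6
        recording, annotation = generate_session(
            protocol=protocol, rng=rng, profiles=subject_profiles,
            subject_id=f"S{k + 1}", bias=bias, fs=fs,
        )
        annotation = replace(annotation, seed=seed)
        cohort.append((recording, annotation))
    return cohort
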