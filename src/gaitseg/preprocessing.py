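"""Inclination correction and causal low-pass filtering.

Inclination correction subtracts the per-channel mean estimated over an
initial standing-still window.  The low-pass filter is a causal IIR
recursion usable sample-by-sample; the default design (order 2, 10 Hz
cutoff at 100 Hz sampling) is the cascade of two identical bilinear
first-order sections and attenuates by more than 15 dB at twice the
corner frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .signal_model import CHANNEL_NAMES, IMURecording

__all__ = [
    "ChannelOffsets",
    "FilterSpec",
    "StreamingFilter",
    "estimate_standing_offset",
    "correct_inclination",
    "design_lowpass",
    "apply_filter_streaming",
    "frequency_response",
]


@dataclass(frozen=True)
class ChannelOffsets:
    """One additive offset per channel, in the channel's own units."""

    ax: float = 0.0
    ay: float = 0.0
    az: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    gz: float = 0.0

    def __post_init__(self):
        for name in CHANNEL_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"offset for {name} is not finite")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CHANNEL_NAMES}


@dataclass(frozen=True)
class FilterSpec:
    """Causal IIR filter ``y[n] = Σ b[k] x[n-k] − Σ a[k] y[n-k]``.

    ``b`` holds the M+1 feed-forward coefficients ``b0..bM``; ``a`` holds
    the N feedback coefficients ``a1..aN`` (the leading unit coefficient
    is implicit).  The spec must have unity DC gain and all recursion
    poles strictly inside the unit circle.
    """

    b: tuple[float, ...]
    a: tuple[float, ...]
    cutoff_hz: float
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        object.__setattr__(self, "a", tuple(float(v) for v in self.a))
        dc = sum(self.b) / (1.0 + sum(self.a))
        if abs(dc - 1.0) > 1e-9:
            raise ValueError(f"DC gain {dc!r} is not unity")
        poles = np.roots([1.0, *self.a]) if self.a else np.array([])
        if poles.size and np.max(np.abs(poles)) >= 1.0:
            raise ValueError("filter is unstable: pole on or outside the unit circle")

    @property
    def order(self) -> int:
        return len(self.a)

    def to_json(self) -> str:
        return json.dumps(
            {"b": list(self.b), "a": list(self.a), "cutoff_hz": self.cutoff_hz, "fs": self.fs}
        )

    @classmethod
    def from_json(cls, payload: str) -> "FilterSpec":
        d = json.loads(payload)
        return cls(b=tuple(d["b"]), a=tuple(d["a"]), cutoff_hz=d["cutoff_hz"], fs=d["fs"])


def estimate_standing_offset(recording: IMURecording, window_s: float = 5.0) -> ChannelOffsets:
    """Per-channel arithmetic mean over the first ``window_s`` seconds."""
    n = int(round(window_s * recording.fs))
    if len(recording) < n:
        raise ValueError(
            f"recording of {len(recording)} samples is shorter than the "
            f"{window_s} s standing window ({n} samples)"
        )
    return ChannelOffsets(
        **{name: float(np.mean(getattr(recording, name)[:n])) for name in CHANNEL_NAMES}
    )


def correct_inclination(recording: IMURecording, offsets: ChannelOffsets) -> IMURecording:
    """Subtract each channel's offset from every sample of that channel."""
    return recording.replace(
        **{name: getattr(recording, name) - getattr(offsets, name) for name in CHANNEL_NAMES}
    )


def _bilinear_first_order(cutoff_hz: float, fs: float) -> tuple[tuple[float, float], tuple[float]]:
    # Single-pole RC prototype H(s) = 1/(1 + s/wc), bilinear transform
    # pre-warped so the digital -3 dB point lands exactly at cutoff_hz.
    wa = math.tan(math.pi * cutoff_hz / fs)
    b0 = wa / (1.0 + wa)
    a1 = (wa - 1.0) / (1.0 + wa)
    return (b0, b0), (a1,)


def design_lowpass(cutoff_hz: float = 10.0, fs: float = 100.0, order: int = 2) -> FilterSpec:
    """Design the causal low-pass filter.

    Order 1 is a bilinear first-order section pre-warped at the cutoff;
    order 2 cascades two identical such sections collapsed into a single
    N = M = 2 recursion.  Both have unity DC gain.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {fs / 2}) Hz")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    b1, a1 = _bilinear_first_order(cutoff_hz, fs)
    if order == 1:
        return FilterSpec(b=b1, a=a1, cutoff_hz=cutoff_hz, fs=fs)
    b = tuple(np.convolve(b1, b1))
    a_full = np.convolve([1.0, *a1], [1.0, *a1])
    return FilterSpec(b=b, a=tuple(a_full[1:]), cutoff_hz=cutoff_hz, fs=fs)


class StreamingFilter:
    """Stateful sample-by-sample applier of a :class:`FilterSpec`.

    History starts at zero; feeding a sequence whole or in chunks yields
    bit-identical output.
    """

    def __init__(self, spec: FilterSpec):
        self.spec = spec
        self._x = [0.0] * len(spec.b)   # x[n], x[n-1], ..., x[n-M]
        self._y = [0.0] * len(spec.a)   # y[n-1], ..., y[n-N]
        self._n = 0

    def push(self, sample: float) -> float:
        if not math.isfinite(sample):
            raise ValueError(f"non-finite input sample at index {self._n}")
        self._x = [float(sample)] + self._x[:-1]
        y = 0.0
        for bk, xk in zip(self.spec.b, self._x):
            y += bk * xk
        for ak, yk in zip(self.spec.a, self._y):
            y -= ak * yk
        if self.spec.a:
            self._y = [y] + self._y[:-1]
        self._n += 1
        return y

    def process(self, samples) -> np.ndarray:
        return np.array([self.push(s) for s in samples], dtype=float)


def apply_filter_streaming(spec: FilterSpec, samples) -> np.ndarray:
    """Filter a whole sequence causally with zero initial history."""
    return StreamingFilter(spec).process(samples)


def frequency_response(spec: FilterSpec, freq_hz: float) -> float:
    """Transfer-function magnitude at ``freq_hz``, in dB."""
    if not 0 <= freq_hz <= spec.fs / 2:
        raise ValueError(f"frequency {freq_hz} Hz outside [0, {spec.fs / 2}] Hz")
    w = 2.0 * math.pi * freq_hz / spec.fs
    z = complex(math.cos(w), -math.sin(w))  # z^{-1} on the unit circle
    num = sum(bk * z**k for k, bk in enumerate(spec.b))
    den = 1.0 + sum(ak * z**k for k, ak in enumerate(spec.a, start=1))
    mag = abs(num / den)
    return 20.0 * math.log10(mag) if mag > 0 else -math.inf


def filter_recording(spec: FilterSpec, recording: IMURecording) -> IMURecording:
    """Filter all six channels independently (zero initial history each)."""
    return recording.replace(
        **{
            name: apply_filter_streaming(spec, getattr(recording, name))
            for name in CHANNEL_NAMES
        }
    )
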