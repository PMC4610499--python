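"""Per-cycle 152-dimensional feature vectors, SVM-weight ranking, top-k.

Eight channels are described: the six sensor axes plus the accelerometer
and gyroscope magnitudes (per-sample Euclidean norms, orientation
independent).  Per channel: six time statistics (mean, median, skewness,
kurtosis, standard deviation, interquartile range) and six spectral
features (Parseval-normalized energy plus the magnitudes of DFT
coefficients 1–5); plus the Pearson correlation of every ordered channel
pair.  48 + 56 + 48 = 152 features with stable names.

Feature ranking scores each feature by the sum of squared primal weights
over all one-vs-one linear SVMs fitted on z-scored features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.svm import SVC

from .signal_model import Segment

__all__ = [
    "FEATURE_CHANNELS",
    "TIME_STATS",
    "FeatureVector",
    "FeatureRanking",
    "feature_names",
    "magnitude",
    "extract_features",
    "rank_features_svm",
    "select_top",
]

#: The eight described channels, in feature-layout order.
FEATURE_CHANNELS = ("ax", "ay", "az", "amag", "gx", "gy", "gz", "gmag")

TIME_STATS = ("mean", "median", "skewness", "kurtosis", "sd", "iqr")

MIN_SEGMENT_LENGTH = 8


def magnitude(x, y, z) -> np.ndarray:
    """Element-wise Euclidean norm of three equal-length channels."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError(
            f"channel lengths differ: {len(x)}, {len(y)}, {len(z)}"
        )
    return np.sqrt(x * x + y * y + z * z)


def feature_names() -> list[str]:
    """The stable 152-entry feature-name registry."""
    names = [f"{stat}_{ch}" for ch in FEATURE_CHANNELS for stat in TIME_STATS]
    names += [
        f"corr_{a}_{b}"
        for a in FEATURE_CHANNELS
        for b in FEATURE_CHANNELS
        if a != b
    ]
    names += [
        f"{spec}_{ch}"
        for ch in FEATURE_CHANNELS
        for spec in ("energy", "fft1", "fft2", "fft3", "fft4", "fft5")
    ]
    assert len(names) == 152
    return names


_FEATURE_NAMES = feature_names()


@dataclass(frozen=True)
class FeatureVector:
    """The 152-dimensional per-cycle descriptor."""

    values: np.ndarray
    names: tuple[str, ...]
    cycle: Optional[object] = None
    activity_label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != 152 or len(self.names) != 152:
            raise ValueError("feature vector must have exactly 152 entries")
        if len(set(self.names)) != 152:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _time_stats(x: np.ndarray) -> list[float]:
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0 or np.ptp(x) == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(_stats.skew(x, bias=True))
        kurt = float(_stats.kurtosis(x, fisher=False, bias=True))
    q75, q25 = np.percentile(x, [75, 25], method="linear")
    return [
        float(np.mean(x)),
        float(np.median(x)),
        skew,
        kurt,
        sd,
        float(q75 - q25),
    ]


def _spectral(x: np.ndarray) -> list[float]:
    n = len(x)
    spec = np.abs(np.fft.fft(x))
    # Parseval normalization: energy equals the time-domain mean square.
    energy = float(np.sum(spec**2)) / (n * n)
    return [energy] + [float(spec[k]) for k in range(1, 6)]


def extract_features(segment: Segment) -> FeatureVector:
    """Compute the 152 named features over a gait-cycle segment.

    Degenerate cases are closed off: zero-variance channels get skewness,
    kurtosis and correlations of 0.
    """
    n = len(segment)
    if n < MIN_SEGMENT_LENGTH:
        raise ValueError(
            f"segment of {n} samples is shorter than the minimum "
            f"{MIN_SEGMENT_LENGTH}"
        )
    chans = {name: segment.channel(name) for name in ("ax", "ay", "az", "gx", "gy", "gz")}
    chans["amag"] = magnitude(chans["ax"], chans["ay"], chans["az"])
    chans["gmag"] = magnitude(chans["gx"], chans["gy"], chans["gz"])

    values: list[float] = []
    for ch in FEATURE_CHANNELS:
        values.extend(_time_stats(chans[ch]))

    sds = {ch: float(np.std(chans[ch])) for ch in FEATURE_CHANNELS}
    for a in FEATURE_CHANNELS:
        for b in FEATURE_CHANNELS:
            if a == b:
                continue
            if sds[a] == 0.0 or sds[b] == 0.0:
                values.append(0.0)
            else:
                xa, xb = chans[a], chans[b]
                cov = float(np.mean((xa - xa.mean()) * (xb - xb.mean())))
                r = cov / (sds[a] * sds[b])
                values.append(min(1.0, max(-1.0, r)))

    for ch in FEATURE_CHANNELS:
        values.extend(_spectral(chans[ch]))

    return FeatureVector(
        values=np.array(values),
        names=tuple(_FEATURE_NAMES),
        cycle=segment,
        activity_label=segment.activity_label,
    )


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by non-increasing squared-weight importance."""

    names: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")
        if any(s < 0 for s in self.scores):
            raise ValueError("scores must be non-negative")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def to_json(self) -> str:
        return json.dumps({"names": list(self.names), "scores": list(self.scores)})

    @classmethod
    def from_json(cls, payload: str) -> "FeatureRanking":
        d = json.loads(payload)
        return cls(names=tuple(d["names"]), scores=tuple(d["scores"]))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd_safe


def rank_features_svm(
    features: np.ndarray,
    labels: Sequence,
    names: Optional[Sequence[str]] = None,
    complexity: float = 1.0,
) -> FeatureRanking:
    """Rank features by summed squared one-vs-one linear-SVM weights.

    Features are z-scored internally (constant columns pass through as
    zeros and receive importance 0).  Ties are broken by name order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if names is None:
        names = _FEATURE_NAMES if X.shape[1] == 152 else [
            f"f{j}" for j in range(X.shape[1])
        ]
    names = list(names)
    if len(set(y)) < 2:
        raise ValueError("feature ranking requires at least two classes")
    Xs = _standardize(X)
    clf = SVC(kernel="linear", C=complexity, decision_function_shape="ovo")
    clf.fit(Xs, y)
    importance = np.sum(np.asarray(clf.coef_) ** 2, axis=0)
    order = sorted(range(len(names)), key=lambda j: (-importance[j], names[j]))
    return FeatureRanking(
        names=tuple(names[j] for j in order),
        scores=tuple(float(importance[j]) for j in order),
    )


def select_top(ranking: FeatureRanking, k: int = 20) -> list[str]:
    """First ``k`` feature names of the ranking."""
    if not 1 <= k <= len(ranking.names):
        raise ValueError(f"k must be in [1, {len(ranking.names)}], got {k}")
    return list(ranking.names[:k])
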