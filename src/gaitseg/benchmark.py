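"""Reproduction harness: headline numbers recomputed from scratch.

Builds a synthetic 9-subject cohort (four activities, ~210 cycles per
subject with standing rests), runs the raw-signal streaming detector and
the LOSO classification chain on it, and reports:

* the magnitude response of the default low-pass design at twice the
  corner frequency (dB);
* the per-cycle feature dimensionality;
* the percentage of annotated gait cycles recovered from raw signals
  (both foot-off boundaries within ±40 ms);
* the leave-one-subject-out average accuracy of the pairwise SVM on
  top-20 features (selection refit per training fold).

Everything is deterministic in the seed.
"""

from __future__ import annotations

import numpy as np

from .activity_classification import ClassifierSpec, loso_evaluate
from .feature_extraction import extract_features, feature_names
from .gait_segmentation import FOOT_OFF, DetectorConfig, cycles_from_events, detect_events
from .pipeline import ACTIVITY_CLASSES, detection_rate
from .preprocessing import design_lowpass, frequency_response
from .synthetic_gait import generate_cohort

__all__ = [
    "ACCEPTANCE_PROTOCOL",
    "build_cohort",
    "segment_cohort",
    "measure_filter_selectivity",
    "measure_feature_count",
    "measure_detection",
    "measure_loso_accuracy",
]

#: ~210 cycles per subject across WK / SA / SD / RUN, mirroring one
#: walk-stairs-run route with standing rests.
ACCEPTANCE_PROTOCOL = (
    ("WK", 50), ("SA", 30), ("WK", 30), ("RUN", 40), ("SD", 30), ("WK", 30),
)

N_SUBJECTS = 9


def build_cohort(seed: int):
    return generate_cohort(N_SUBJECTS, protocol=ACCEPTANCE_PROTOCOL, seed=seed)


def segment_cohort(cohort):
    """Raw-signal event detection for every recording (no pre-processing)."""
    config = DetectorConfig(fs=cohort[0][0].fs)
    return [detect_events(recording.gz, config) for recording, _ in cohort]


def measure_filter_selectivity(cutoff_hz: float = 10.0, fs: float = 100.0) -> float:
    """Gain in dB of the default order-2 design at twice the cutoff."""
    spec = design_lowpass(cutoff_hz, fs, order=2)
    return frequency_response(spec, 2 * cutoff_hz)


def measure_feature_count(seed: int) -> int:
    """Number of named features extracted from one synthetic gait cycle."""
    cohort = generate_cohort(1, protocol=(("WK", 2),), seed=seed)
    recording, _ = cohort[0]
    events = detect_events(recording.gz, DetectorConfig(fs=recording.fs))
    cycles = cycles_from_events(events, recording)
    fv = extract_features(cycles[0].segment)
    assert len(fv.names) == len(fv.values)
    return len(fv.values)


def measure_detection(cohort, events_per_recording) -> tuple[float, int]:
    """Pooled % of annotated cycles with both foot-offs within ±40 ms."""
    total_detected = 0
    total_annotated = 0
    for (_, annotation), events in zip(cohort, events_per_recording):
        foot_offs = np.array(
            [e.time_s for e in events if e.event_type == FOOT_OFF]
        )
        detected, annotated = detection_rate(foot_offs, annotation)
        total_detected += sum(detected.values())
        total_annotated += sum(annotated.values())
    return 100.0 * total_detected / total_annotated, total_annotated


def measure_loso_accuracy(cohort, events_per_recording) -> tuple[float, int]:
    """LOSO average accuracy (%) on top-20 features of raw-segmented cycles."""
    X, y, subjects = [], [], []
    for (recording, _), events in zip(cohort, events_per_recording):
        for cycle in cycles_from_events(events, recording):
            if cycle.activity_label not in ACTIVITY_CLASSES:
                continue
            if len(cycle.segment) < 8:
                continue
            X.append(extract_features(cycle.segment).values)
            y.append(cycle.activity_label)
            subjects.append(recording.subject_id)
    report = loso_evaluate(
        np.vstack(X), y, subjects,
        spec=ClassifierSpec(select_top_k=20),
        feature_names=feature_names(),
    )
    return report.average_accuracy, len(y)
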