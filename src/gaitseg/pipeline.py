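"""End-to-end orchestration of the six pre-processing configurations.

Configurations combine inclination correction (off / on, applied before
segmentation) with low-pass filtering (off / applied per segment after
raw segmentation / applied to the whole signal before segmentation):

1. raw; 2. inclination only; 3. raw segmentation + segment filtering;
4. inclination + segment filtering; 5. filtering only;
6. inclination + filtering.

Configurations sharing a segmentation input (1 & 3, 2 & 4) share event
lists.  Segment-window filtering resets the filter state per window.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .activity_classification import (
    ClassifierSpec,
    EvaluationReport,
    loso_evaluate,
)
from .feature_extraction import extract_features, feature_names
from .gait_segmentation import (
    FOOT_OFF,
    DetectorConfig,
    GaitCycle,
    cycles_from_events,
    detect_events,
)
from .preprocessing import (
    FilterSpec,
    apply_filter_streaming,
    correct_inclination,
    design_lowpass,
    estimate_standing_offset,
    filter_recording,
)
from .signal_model import CHANNEL_NAMES, IMURecording, Segment
from .synthetic_gait import SyntheticAnnotation

__all__ = [
    "PipelineConfiguration",
    "PIPELINE_CONFIGURATIONS",
    "ComparisonReport",
    "run_configuration",
    "run_comparison",
    "detection_rate",
]

logger = logging.getLogger(__name__)

ACTIVITY_CLASSES = ("WK", "SA", "SD", "RUN")

#: Matching tolerance for a detected foot-off against ground truth.
DETECTION_TOLERANCE_S = 0.040


@dataclass(frozen=True)
class PipelineConfiguration:
    """One of the six pre-processing configurations."""

    id: int
    inclination_correction: str  # {"none", "before_segmentation"}
    filtering: str  # {"none", "on_segments_after_raw_segmentation", "before_segmentation"}
    name: str = ""

    _VALID = {
        1: ("none", "none"),
        2: ("before_segmentation", "none"),
        3: ("none", "on_segments_after_raw_segmentation"),
        4: ("before_segmentation", "on_segments_after_raw_segmentation"),
        5: ("none", "before_segmentation"),
        6: ("before_segmentation", "before_segmentation"),
    }

    def __post_init__(self):
        expected = self._VALID.get(self.id)
        if expected is None:
            raise ValueError(f"unknown configuration id {self.id}; valid ids are 1-6")
        if (self.inclination_correction, self.filtering) != expected:
            raise ValueError(
                f"configuration {self.id} must be "
                f"inclination={expected[0]!r}, filtering={expected[1]!r}"
            )

    @classmethod
    def from_id(cls, config_id: int) -> "PipelineConfiguration":
        names = {
            1: "raw",
            2: "inclination only",
            3: "raw segmentation + segment filtering",
            4: "inclination + segment filtering",
            5: "filtering only",
            6: "inclination + filtering",
        }
        if config_id not in cls._VALID:
            raise ValueError(f"unknown configuration id {config_id}; valid ids are 1-6")
        incl, filt = cls._VALID[config_id]
        return cls(id=config_id, inclination_correction=incl, filtering=filt,
                   name=names[config_id])


PIPELINE_CONFIGURATIONS = tuple(PipelineConfiguration.from_id(i) for i in range(1, 7))


def detection_rate(
    detected_foot_off_times: np.ndarray,
    annotation: SyntheticAnnotation,
    tolerance_s: float = DETECTION_TOLERANCE_S,
) -> tuple[dict[str, int], dict[str, int]]:
    """Count annotated cycles recovered by the detector, per activity.

    A cycle counts as detected when a *consecutive* pair of detected
    foot-off events matches both of its boundary foot-offs within the
    tolerance.  Returns (detected counts, annotated counts) per activity.
    """
    u = np.sort(np.asarray(detected_foot_off_times, dtype=float))
    detected: dict[str, int] = {}
    annotated: dict[str, int] = {}
    for cyc in annotation.cycles:
        annotated[cyc.activity] = annotated.get(cyc.activity, 0) + 1
        ok = False
        if len(u) >= 2:
            j = int(np.searchsorted(u, cyc.start_foot_off_s))
            for i in (j - 1, j):
                if 0 <= i < len(u) - 1:
                    if (
                        abs(u[i] - cyc.start_foot_off_s) <= tolerance_s
                        and abs(u[i + 1] - cyc.end_foot_off_s) <= tolerance_s
                    ):
                        ok = True
                        break
        if ok:
            detected[cyc.activity] = detected.get(cyc.activity, 0) + 1
    return detected, annotated


def _preprocess_for_segmentation(
    recording: IMURecording,
    config: PipelineConfiguration,
    filter_spec: FilterSpec,
    standing_window_s: float,
) -> IMURecording:
    out = recording
    if config.inclination_correction == "before_segmentation":
        offsets = estimate_standing_offset(out, standing_window_s)
        out = correct_inclination(out, offsets)
    if config.filtering == "before_segmentation":
        out = filter_recording(filter_spec, out)
    return out


def _filtered_window_segment(
    segment: Segment, filter_spec: FilterSpec
) -> Segment:
    # independent post-hoc filtering of one cycle window, zero history
    rec = segment.recording
    n = len(segment)
    data = {
        name: apply_filter_streaming(filter_spec, segment.channel(name))
        for name in CHANNEL_NAMES
    }
    labels = segment.labels if rec.has_labels else np.empty(0, dtype=object)
    window = IMURecording(
        time=np.arange(n) / rec.fs, fs=rec.fs, labels=labels,
        subject_id=rec.subject_id, **data,
    )
    return Segment(window, 0, n, activity_label=segment.activity_label)


def _cycle_features(
    cycles: Sequence[GaitCycle],
    config: PipelineConfiguration,
    filter_spec: FilterSpec,
    subject_id: str,
):
    rows, labels, subjects = [], [], []
    for cycle in cycles:
        if cycle.activity_label not in ACTIVITY_CLASSES:
            continue
        if len(cycle.segment) < 8:
            continue
        segment = cycle.segment
        if config.filtering == "on_segments_after_raw_segmentation":
            segment = _filtered_window_segment(segment, filter_spec)
        fv = extract_features(segment)
        rows.append(fv.values)
        labels.append(cycle.activity_label)
        subjects.append(subject_id)
    return rows, labels, subjects


def run_configuration(
    config: PipelineConfiguration,
    data: Sequence[tuple[IMURecording, Optional[SyntheticAnnotation]]],
    detector_config: Optional[DetectorConfig] = None,
    classifier_spec: Optional[ClassifierSpec] = None,
    filter_spec: Optional[FilterSpec] = None,
    standing_window_s: float = 5.0,
    events_cache: Optional[dict] = None,
) -> tuple[EvaluationReport, Optional[float]]:
    """Run one configuration end-to-end over labeled recordings.

    Returns the LOSO evaluation report and the pooled cycle-detection
    rate in percent (None when no annotations are supplied).
    """
    if detector_config is None:
        detector_config = DetectorConfig(fs=data[0][0].fs)
    if classifier_spec is None:
        classifier_spec = ClassifierSpec(select_top_k=20)
    if filter_spec is None:
        filter_spec = design_lowpass(fs=data[0][0].fs)

    X_rows, y, subjects = [], [], []
    det_counts: dict[str, int] = {}
    ann_counts: dict[str, int] = {}
    have_annotations = True
    for recording, annotation in data:
        if not recording.has_labels:
            raise ValueError("recordings must carry activity labels")
        processed = _preprocess_for_segmentation(
            recording, config, filter_spec, standing_window_s
        )
        cache_key = (
            id(recording),
            config.inclination_correction,
            config.filtering == "before_segmentation",
        )
        if events_cache is not None and cache_key in events_cache:
            events = events_cache[cache_key]
        else:
            events = detect_events(processed.gz, detector_config)
            if events_cache is not None:
                events_cache[cache_key] = events
        cycles = cycles_from_events(events, processed)
        rows, labels, subs = _cycle_features(
            cycles, config, filter_spec, recording.subject_id
        )
        X_rows.extend(rows)
        y.extend(labels)
        subjects.extend(subs)
        if annotation is None:
            have_annotations = False
        else:
            fo_times = np.array(
                [e.time_s for e in events if e.event_type == FOOT_OFF]
            )
            d, a = detection_rate(fo_times, annotation)
            for k, v in d.items():
                det_counts[k] = det_counts.get(k, 0) + v
            for k, v in a.items():
                ann_counts[k] = ann_counts.get(k, 0) + v

    X = np.vstack(X_rows)
    report = loso_evaluate(
        X, y, subjects, spec=classifier_spec, feature_names=feature_names()
    )
    rate = None
    if have_annotations and ann_counts:
        total_ann = sum(ann_counts.values())
        total_det = sum(det_counts.values())
        rate = 100.0 * total_det / total_ann
        report.step_detection = {
            k: (100.0 * det_counts.get(k, 0) / v if v else None)
            for k, v in sorted(ann_counts.items())
        }
    return report, rate


@dataclass
class ComparisonReport:
    """Per-configuration evaluation over identical inputs and folds."""

    reports: dict[int, EvaluationReport]
    detection_rates: dict[int, Optional[float]]
    seed: Optional[int] = None
    config_hash: str = ""

    def __post_init__(self):
        if sorted(self.reports) != list(range(1, 7)):
            raise ValueError("comparison must cover configurations 1-6")

    def accuracy_spread(self) -> float:
        accs = [r.average_accuracy for r in self.reports.values()]
        return max(accs) - min(accs)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "configurations": {
                str(i): {
                    "name": PipelineConfiguration.from_id(i).name,
                    "detection_rate": self.detection_rates.get(i),
                    "report": self.reports[i].to_dict(),
                }
                for i in sorted(self.reports)
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            reports={
                int(i): EvaluationReport.from_dict(v["report"])
                for i, v in d["configurations"].items()
            },
            detection_rates={
                int(i): v["detection_rate"]
                for i, v in d["configurations"].items()
            },
            seed=d.get("seed"),
            config_hash=d.get("config_hash", ""),
        )


def run_comparison(
    data: Sequence[tuple[IMURecording, Optional[SyntheticAnnotation]]],
    detector_config: Optional[DetectorConfig] = None,
    classifier_spec: Optional[ClassifierSpec] = None,
    filter_spec: Optional[FilterSpec] = None,
    seed: Optional[int] = None,
) -> ComparisonReport:
    """Run all six configurations on identical inputs and folds."""
    if detector_config is None:
        detector_config = DetectorConfig(fs=data[0][0].fs)
    if classifier_spec is None:
        classifier_spec = ClassifierSpec(select_top_k=20)
    if filter_spec is None:
        filter_spec = design_lowpass(fs=data[0][0].fs)
    payload = json.dumps(
        {
            "detector": vars(detector_config) if hasattr(detector_config, "__dict__")
            else {f: getattr(detector_config, f)
                  for f in detector_config.__dataclass_fields__},
            "classifier": {f: getattr(classifier_spec, f)
                           for f in classifier_spec.__dataclass_fields__},
            "filter": {"b": list(filter_spec.b), "a": list(filter_spec.a),
                       "cutoff_hz": filter_spec.cutoff_hz, "fs": filter_spec.fs},
            "seed": seed,
        },
        sort_keys=True,
    )
    config_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]
    reports: dict[int, EvaluationReport] = {}
    rates: dict[int, Optional[float]] = {}
    events_cache: dict = {}
    for cfg in PIPELINE_CONFIGURATIONS:
        logger.info("running configuration %d (%s)", cfg.id, cfg.name)
        report, rate = run_configuration(
            cfg, data, detector_config, classifier_spec, filter_spec,
            events_cache=events_cache,
        )
        reports[cfg.id] = report
        rates[cfg.id] = rate
    return ComparisonReport(
        reports=reports, detection_rates=rates, seed=seed, config_hash=config_hash
    )
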