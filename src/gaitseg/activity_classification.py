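"""Pairwise SVM activity classification and evaluation protocols.

A multi-class model is one soft-margin polynomial-kernel machine per
unordered class pair on z-scored features, predicting by majority vote
with ties broken toward the larger aggregate decision margin.  Two
protocols are provided: leave-one-subject-out (one fold per subject,
standardization and optional feature selection refit per training split)
and a single cross-dataset train/test split.  Metrics follow the usual
confusion-matrix collapse: per-class sensitivity and specificity plus
overall accuracy, all in percent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_extraction import rank_features_svm, select_top

__all__ = [
    "ClassifierSpec",
    "Model",
    "EvaluationReport",
    "train_classifier",
    "loso_evaluate",
    "cross_dataset_evaluate",
    "confusion_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierSpec:
    """Polynomial-kernel pairwise SVM configuration."""

    kernel: str = "poly"
    degree: int = 1
    complexity: float = 1.0
    select_top_k: Optional[int] = None  # per-fold feature selection when set

    def __post_init__(self):
        if self.complexity <= 0:
            raise ValueError("complexity must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


class Model:
    """Fitted pairwise classifier with its standardization and selection."""

    def __init__(self, spec: ClassifierSpec, scaler: StandardScaler,
                 svc: SVC, classes: np.ndarray,
                 selected_indices: Optional[np.ndarray] = None,
                 selected_names: Optional[list[str]] = None):
        self.spec = spec
        self.scaler = scaler
        self.svc = svc
        self.classes = classes
        self.selected_indices = selected_indices
        self.selected_names = selected_names

    @property
    def n_pairwise_machines(self) -> int:
        k = len(self.classes)
        return k * (k - 1) // 2

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.selected_indices is not None:
            X = X[:, self.selected_indices]
        return self.svc.predict(self.scaler.transform(X))


def train_classifier(
    features: np.ndarray,
    labels: Sequence,
    spec: Optional[ClassifierSpec] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> Model:
    """Fit one binary machine per unordered class pair on z-scored features.

    Prediction uses one-vs-one majority voting; vote ties are resolved by
    the aggregate pairwise decision margin.  When ``spec.select_top_k``
    is set, squared-weight feature ranking is fitted on the same data and
    only the top-k features enter the classifier.
    """
    if spec is None:
        spec = ClassifierSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")

    selected_indices = None
    selected_names = None
    if spec.select_top_k is not None:
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{j}" for j in range(X.shape[1])]
        )
        ranking = rank_features_svm(X, y, names=names)
        selected_names = select_top(ranking, spec.select_top_k)
        selected_indices = np.array([names.index(n) for n in selected_names])
        X = X[:, selected_indices]

    scaler = StandardScaler().fit(X)
    # decision_function_shape='ovo' keeps the raw pairwise votes; SVC's
    # predict breaks vote ties by the summed decision values, matching
    # the aggregate-margin rule.
    svc = SVC(
        kernel=spec.kernel,
        degree=spec.degree,
        C=spec.complexity,
        gamma=1.0,
        coef0=1.0,
        decision_function_shape="ovo",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svc.fit(scaler.transform(X), y)
    return Model(spec, scaler, svc, np.unique(y), selected_indices, selected_names)


@dataclass
class EvaluationReport:
    """Aggregate evaluation results.

    The confusion matrix is row-normalized to percent (row = true class);
    raw counts are kept alongside.  Step-detection ratios are attached by
    the pipeline when ground-truth annotations exist.
    """

    classes: list[str]
    fold_accuracies: list[float]          # %
    average_accuracy: float               # %
    accuracy_sd: float                    # % across folds
    confusion_counts: list[list[int]]
    confusion_percent: list[list[float]]  # row-normalized
    specificity: dict[str, Optional[float]]
    sensitivity: dict[str, Optional[float]]
    step_detection: dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "fold_accuracies": self.fold_accuracies,
            "average_accuracy": self.average_accuracy,
            "accuracy_sd": self.accuracy_sd,
            "confusion_counts": self.confusion_counts,
            "confusion_percent": self.confusion_percent,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "step_detection": self.step_detection,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)


def confusion_metrics(matrix: np.ndarray) -> dict:
    """Per-class specificity/sensitivity and overall accuracy, in percent.

    ``matrix[i, j]`` counts true class i predicted as class j.  A class
    with an empty row gets ``None`` (undefined), not zero.
    """
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = M.sum()
    k = M.shape[0]
    sens: list[Optional[float]] = []
    spec: list[Optional[float]] = []
    for c in range(k):
        row = M[c].sum()
        tp = M[c, c]
        fp = M[:, c].sum() - tp
        tn = total - row - fp
        sens.append(float(100.0 * tp / row) if row > 0 else None)
        spec.append(float(100.0 * tn / (tn + fp)) if (tn + fp) > 0 else None)
    accuracy = float(100.0 * np.trace(M) / total) if total > 0 else None
    return {"sensitivity": sens, "specificity": spec, "accuracy": accuracy}


def _row_normalize_percent(M: np.ndarray) -> list[list[float]]:
    out = []
    for row in np.asarray(M, dtype=float):
        s = row.sum()
        out.append([100.0 * v / s if s > 0 else 0.0 for v in row])
    return out


def _build_report(
    classes: list,
    fold_accuracies: list[float],
    confusion: np.ndarray,
) -> EvaluationReport:
    metrics = confusion_metrics(confusion)
    return EvaluationReport(
        classes=[str(c) for c in classes],
        fold_accuracies=[float(a) for a in fold_accuracies],
        average_accuracy=float(np.mean(fold_accuracies)),
        accuracy_sd=float(np.std(fold_accuracies, ddof=1)) if len(fold_accuracies) > 1 else 0.0,
        confusion_counts=np.asarray(confusion, dtype=int).tolist(),
        confusion_percent=_row_normalize_percent(confusion),
        specificity={str(c): metrics["specificity"][i] for i, c in enumerate(classes)},
        sensitivity={str(c): metrics["sensitivity"][i] for i, c in enumerate(classes)},
    )


def loso_evaluate(
    features: np.ndarray,
    labels: Sequence,
    subject_ids: Sequence,
    spec: Optional[ClassifierSpec] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation: one fold per subject.

    Standardization and any top-k feature selection are refit on each
    training split only; the reported accuracy is the across-fold mean.
    Folds whose subject has no samples are skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    subjects = np.asarray(subject_ids)
    unique_subjects = list(dict.fromkeys(subjects.tolist()))
    if len(unique_subjects) < 2:
        raise ValueError("LOSO requires at least two subjects")
    classes = sorted(set(str(v) for v in y))
    class_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc: list[float] = []
    for subject in unique_subjects:
        test_mask = subjects == subject
        if not np.any(test_mask):
            logger.warning("subject %s has no cycles; fold skipped", subject)
            continue
        model = train_classifier(X[~test_mask], y[~test_mask], spec, feature_names)
        pred = model.predict(X[test_mask])
        truth = y[test_mask]
        fold_acc.append(100.0 * float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            confusion[class_index[str(t)], class_index[str(p)]] += 1
    return _build_report(classes, fold_acc, confusion)


def cross_dataset_evaluate(
    train_features: np.ndarray,
    train_labels: Sequence,
    test_features: np.ndarray,
    test_labels: Sequence,
    spec: Optional[ClassifierSpec] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Train on one dataset, test on another (test labels ⊆ train labels)."""
    y_train = np.asarray(train_labels)
    y_test = np.asarray(test_labels)
    unseen = set(str(v) for v in y_test) - set(str(v) for v in y_train)
    if unseen:
        raise ValueError(f"test labels absent from training: {sorted(unseen)}")
    model = train_classifier(train_features, y_train, spec, feature_names)
    pred = model.predict(np.asarray(test_features, dtype=float))
    # cover test classes plus any stray out-of-set predictions
    classes = sorted(set(str(v) for v in y_test) | set(str(v) for v in pred))
    class_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_test, pred):
        confusion[class_index[str(t)], class_index[str(p)]] += 1
    accuracy = 100.0 * float(np.mean(pred.astype(str) == y_test.astype(str)))
    return _build_report(classes, [accuracy], confusion)
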