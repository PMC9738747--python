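"""Feature assembly and classifier evaluation on ApEn feature vectors.

Each patient is summarised by 12 approximate-entropy values — one per
(SOT condition, COP axis) combination — and those 12 numbers are the entire
feature space.  Two classification approaches are evaluated:

* ``binary_over47`` — NormalBalance vs TBI among patients older than 47
  years (the pair the screening stage selects), positive class TBI;
* ``fourclass_all`` — all four diagnosis classes on the whole cohort,
  macro-averaged metrics.

Model fitting delegates to scikit-learn (logistic regression with L2
penalty, random forest, linear discriminant analysis, RBF-kernel SVM, all at
library defaults with fixed seeds); the stratified hold-out split, the
metric arithmetic, and report assembly are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .synthetic import AXES, CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "MODEL_FAMILIES",
    "Metrics",
    "ClassifierReport",
    "assemble_features",
    "stratified_split",
    "compute_metrics",
    "train_and_evaluate",
    "evaluate_models",
]

#: Canonical feature ordering: condition-major, ML before AP.
FEATURE_COLUMNS = [f"c{cond}_{axis}" for cond in CONDITIONS for axis in AXES]

MODEL_FAMILIES = ("LR", "RF", "LDA", "SVM")

DEFAULT_TEST_SIZE = 0.2
DEFAULT_POSITIVE_CLASS = "TBI"


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class ClassifierReport:
    """Per-model metric table for one approach (the published-table shape)."""

    approach: str
    averaging: str
    split: str
    entries: dict[str, Metrics] = field(default_factory=dict)

    def to_frame(self, as_percent: bool = True) -> pd.DataFrame:
        rows = {}
        for family, m in self.entries.items():
            vals = [m.accuracy, m.precision, m.recall, m.f1]
            if as_percent:
                vals = [round(100.0 * v, 2) for v in vals]
            rows[family] = vals
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["accuracy", "precision", "recall", "f1"]
        )

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "averaging": self.averaging,
            "split": self.split,
            "metrics": {
                family: {
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
                for family, m in self.entries.items()
            },
        }


def assemble_features(apen_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-trial ApEn records into one 12-column row per patient.

    ``apen_table`` needs columns ``patient_id``, ``condition``, ``axis``,
    ``apen``.  Duplicate (patient, condition, axis) records are an error;
    patients missing any of the 12 entries are excluded with a log message.
    """
    required = {"patient_id", "condition", "axis", "apen"}
    missing = required - set(apen_table.columns)
    if missing:
        raise ValueError(f"apen table missing columns: {sorted(missing)}")
    if apen_table.empty:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    dup_mask = apen_table.duplicated(["patient_id", "condition", "axis"], keep=False)
    if dup_mask.any():
        first = apen_table.loc[dup_mask, ["patient_id", "condition", "axis"]].iloc[0]
        raise ValueError(
            "duplicate ApEn record for "
            f"(patient={first['patient_id']}, condition={first['condition']}, "
            f"axis={first['axis']})"
        )
    table = apen_table.assign(
        feature=[
            f"c{c}_{a}" for c, a in zip(apen_table["condition"], apen_table["axis"])
        ]
    )
    wide = table.pivot(index="patient_id", columns="feature", values="apen")
    wide = wide.reindex(columns=FEATURE_COLUMNS)
    complete = wide.notna().all(axis=1)
    incomplete_ids = wide.index[~complete].tolist()
    if incomplete_ids:
        logger.warning(
            "%d patient(s) with incomplete feature vectors excluded: %s",
            len(incomplete_ids),
            incomplete_ids[:10],
        )
    return wide.loc[complete].astype(float)


def stratified_split(
    labels: np.ndarray, test_size: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified hold-out split (own implementation).

    Within each class the indices are shuffled and ``round(n * test_size)``
    (at least 1, at most n-1) go to the test set.
    """
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < 2:
            raise ValueError(
                f"class {label!r} has {idx.size} sample(s); need >= 2 to split"
            )
        idx = rng.permutation(idx)
        n_test = int(round(idx.size * test_size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _binary_counts(y_true, y_pred, positive):
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    return tp, fp, fn


def compute_metrics(
    y_true,
    y_pred,
    averaging: str = "binary",
    positive_class=None,
) -> Metrics:
    """Accuracy, precision, recall and f1, computed from first principles.

    Binary: precision/recall of the declared positive class, f1 their
    harmonic mean.  Macro: unweighted means of per-class precision, recall
    and f1 (macro-f1 averages per-class f1 rather than taking the harmonic
    mean of macro precision/recall).  Undefined precision (no predicted
    positives) is 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    accuracy = float(np.mean(y_true == y_pred))

    def prf(positive):
        tp, fp, fn = _binary_counts(y_true, y_pred, positive)
        if tp + fp == 0:
            warnings.warn(
                f"no predicted positives for class {positive!r}: precision set to 0",
                stacklevel=3,
            )
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return precision, recall, f1

    if averaging == "binary":
        if positive_class is None:
            raise ValueError("binary averaging requires a positive_class")
        precision, recall, f1 = prf(positive_class)
    elif averaging == "macro":
        per_class = [prf(c) for c in np.unique(y_true)]
        precision = float(np.mean([p for p, _, _ in per_class]))
        recall = float(np.mean([r for _, r, _ in per_class]))
        f1 = float(np.mean([f for _, _, f in per_class]))
    else:
        raise ValueError("averaging must be 'binary' or 'macro'")
    return Metrics(accuracy, float(precision), float(recall), float(f1))


def _make_model(family: str, seed: int):
    if family == "LR":
        return LogisticRegression(penalty="l2", max_iter=5000, random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed)
    if family == "LDA":
        return LinearDiscriminantAnalysis()
    if family == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


def train_and_evaluate(
    features: pd.DataFrame,
    labels,
    family: str,
    seed: int,
    test_size: float = DEFAULT_TEST_SIZE,
    averaging: str | None = None,
    positive_class=DEFAULT_POSITIVE_CLASS,
) -> Metrics:
    """Fit one model family on a stratified hold-out split and score it.

    ``averaging`` defaults to binary when exactly two classes are present,
    macro otherwise.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to classify")
    if averaging is None:
        averaging = "binary" if classes.size == 2 else "macro"
    rng = np.random.default_rng(seed)
    train_idx, test_idx = stratified_split(y, test_size, rng)
    if np.unique(y[train_idx]).size < classes.size:
        raise ValueError(
            "a class is absent from the training split; use a different seed "
            "or more data"
        )
    model = _make_model(family, seed)
    model.fit(X[train_idx], y[train_idx])
    y_pred = model.predict(X[test_idx])
    return compute_metrics(
        y[test_idx],
        y_pred,
        averaging=averaging,
        positive_class=positive_class if averaging == "binary" else None,
    )


def evaluate_models(
    features: pd.DataFrame,
    labels,
    approach: str,
    seed: int,
    families=MODEL_FAMILIES,
    test_size: float = DEFAULT_TEST_SIZE,
    positive_class=DEFAULT_POSITIVE_CLASS,
) -> ClassifierReport:
    """Run every requested model family under one approach and collect the
    metric table."""
    y = np.asarray(labels)
    averaging = "binary" if np.unique(y).size == 2 else "macro"
    report = ClassifierReport(
        approach=approach,
        averaging=(
            f"binary (positive={positive_class})" if averaging == "binary" else "macro"
        ),
        split=f"stratified hold-out, test fraction {test_size}, seed {seed}",
    )
    for family in families:
        report.entries[family] = train_and_evaluate(
            features,
            y,
            family,
            seed=seed,
            test_size=test_size,
            averaging=averaging,
            positive_class=positive_class,
        )
        logger.info("%s/%s: %s", approach, family, report.entries[family])
    return report
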