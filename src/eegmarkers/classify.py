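"""Multiclass maximum-margin classification of the state of consciousness.

Feature sets mirror the analysis design: ``alpha`` = the five alpha-peak
measures plus the two non-peak extrema (7 columns, rows restricted to alpha
peaks), ``acw`` = the three autocorrelation windows (3 columns, all rows),
``combined`` = both (10 columns, alpha rows).  Each (recording, ROI) row is
an independent datapoint; the two-class task collapses MCS and UWS into DOC.

The classifier is a linear-kernel SVM with unit box constraint wrapped in
one-vs-one coding (N(N-1)/2 binary models, majority-vote decoding),
evaluated with stratified 10-fold cross-validation.  Features are
standardized inside each training fold only (no test leakage).  Accuracy,
precision, recall and F1 are averaged over folds; the confusion matrix is
pooled across folds; AUC is macro one-vs-rest from decision scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsOneClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "ALPHA_FEATURES",
    "ACW_FEATURES",
    "build_features",
    "crossval_ovo",
    "report_metrics",
]

ALPHA_FEATURES = ["power", "frequency", "prominence", "width", "power_ratio",
                  "max_power", "min_power"]
ACW_FEATURES = ["acw50", "acw_e", "acw0"]


@dataclass
class FeatureMatrix:
    """Numeric features plus one label per row."""

    X: np.ndarray
    y: np.ndarray  # class labels (strings)
    feature_names: list[str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise InvalidArgumentError("X and y shapes disagree")
        if np.isnan(self.X).any():
            raise InvalidArgumentError("feature matrix contains missing values")
        if not self.classes:
            self.classes = sorted(set(self.y))


@dataclass
class ClassificationReport:
    """Cross-validated performance summary."""

    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # pooled across folds, rows = true classes
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_auc: float
    n_folds: int
    seed: int
    n_binary_models: int


def build_features(
    table: pd.DataFrame, feature_set: str = "combined", task: str = "two_class"
) -> FeatureMatrix:
    """Assemble a feature matrix from a subject table.

    Rows lacking an alpha peak are excluded from the ``alpha`` and
    ``combined`` sets (their peak measures do not exist); the ``acw`` set
    uses every row with uncensored ACWs.
    """
    if feature_set not in ("alpha", "acw", "combined"):
        raise InvalidArgumentError(f"unknown feature_set {feature_set!r}")
    if task not in ("two_class", "three_class"):
        raise InvalidArgumentError(f"unknown task {task!r}")
    rows = table
    if feature_set in ("alpha", "combined"):
        rows = rows[rows["band"] == "alpha"]
        cols = ALPHA_FEATURES + (ACW_FEATURES if feature_set == "combined" else [])
    else:
        cols = list(ACW_FEATURES)
    if "censored_any" in rows.columns:
        rows = rows[~rows["censored_any"].astype(bool)]
    rows = rows.dropna(subset=cols)
    if rows.empty:
        raise InsufficientDataError(
            f"no usable rows for feature set {feature_set!r}"
        )
    labels = rows["group"].astype(str).to_numpy(dtype=object)
    if task == "two_class":
        labels = np.where(labels == "control", "control", "DOC")
    return FeatureMatrix(X=rows[cols].to_numpy(dtype=float), y=labels,
                         feature_names=list(cols))


def crossval_ovo(
    features: FeatureMatrix, k_folds: int = 10, seed: int = 0
) -> ClassificationReport:
    """Stratified k-fold CV of a one-vs-one linear SVM on ``features``."""
    classes = sorted(set(features.y))
    if len(classes) < 2:
        raise InvalidArgumentError("need at least two classes")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in features.y])
    min_count = int(np.bincount(y_idx).min())
    if min_count < 2:
        raise InsufficientDataError(
            "every class needs at least 2 members for cross-validation"
        )
    folds = k_folds
    if min_count < k_folds:
        folds = max(2, min_count)
        warnings.warn(
            f"smallest class has {min_count} members; folds reduced to {folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_classes = len(classes)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    fold_acc: list[float] = []
    scores = np.zeros((features.y.size, n_classes))
    n_binary = 0
    for train, test in skf.split(features.X, y_idx):
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svm", OneVsOneClassifier(SVC(kernel="linear", C=1.0))),
        ])
        model.fit(features.X[train], y_idx[train])
        n_binary = len(model.named_steps["svm"].estimators_)
        pred = model.predict(features.X[test])
        fold_acc.append(float(np.mean(pred == y_idx[test])))
        dec = model.decision_function(features.X[test])
        if dec.ndim == 1:  # binary: single margin column -> two-column scores
            scores[test, 1] = dec
            scores[test, 0] = -dec
        else:
            scores[test] = dec
        for t, p in zip(y_idx[test], pred):
            confusion[t, p] += 1

    report = report_metrics(confusion, classes)
    aucs = []
    for i in range(n_classes):
        true = (y_idx == i).astype(int)
        if true.min() == true.max():
            continue
        aucs.append(roc_auc_score(true, scores[:, i]))
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return ClassificationReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        sd_accuracy=float(np.std(fold_acc, ddof=1)) if len(fold_acc) > 1 else 0.0,
        confusion=confusion, classes=classes,
        precision=report["precision"], recall=report["recall"], f1=report["f1"],
        macro_auc=macro_auc, n_folds=folds, seed=seed, n_binary_models=n_binary,
    )


def report_metrics(confusion: np.ndarray, classes: list[str] | None = None) -> dict:
    """Per-class precision/recall/F1 from a pooled confusion matrix.

    Rows are true classes, columns predicted.  Ratios with a zero denominator
    are reported as 0 with a warning.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise InvalidArgumentError("confusion matrix must be square")
    if np.any(confusion < 0):
        raise InvalidArgumentError("confusion matrix counts must be non-negative")
    n = confusion.shape[0]
    classes = classes or [str(i) for i in range(n)]
    precision, recall, f1 = {}, {}, {}
    for i, cls in enumerate(classes):
        tp = confusion[i, i]
        col = confusion[:, i].sum()
        row = confusion[i, :].sum()
        if col == 0:
            warnings.warn(f"class {cls!r} never predicted; precision set to 0")
            precision[cls] = 0.0
        else:
            precision[cls] = float(tp / col)
        if row == 0:
            warnings.warn(f"class {cls!r} has no true members; recall set to 0")
            recall[cls] = 0.0
        else:
            recall[cls] = float(tp / row)
        denom = precision[cls] + recall[cls]
        f1[cls] = float(2 * precision[cls] * recall[cls] / denom) if denom else 0.0
    accuracy = float(np.trace(confusion) / confusion.sum()) if confusion.sum() else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}
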