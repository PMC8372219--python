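"""Held-out model evaluation: AUROC, threshold metrics, and curve data.

The ROC curve is computed by a descending-score threshold sweep with tied
scores grouped into a single step, and AUROC as the trapezoidal area under
that curve.  This is exactly the Mann-Whitney U statistic divided by
``n_pos * n_neg`` with ties counted 1/2: the probability that a random
positive outscores a random negative.

The positive class is, by convention, the lexicographically second outcome
level unless overridden; every output that mentions a class echoes this
choice.  Threshold-based metrics (accuracy, F1, sensitivity, specificity)
use a cut-off of 0.5 on the positive-class score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .core_data import DataError

#: Direction of each supported metric: True when larger is better.
GREATER_IS_BETTER = {
    "auroc": True,
    "auprc": True,
    "accuracy": True,
    "balanced_accuracy": True,
    "f1": True,
    "sensitivity": True,
    "specificity": True,
    "rmse": False,
    "mae": False,
    "r2": True,
}

CLASSIFICATION_METRICS = (
    "auroc",
    "auprc",
    "accuracy",
    "balanced_accuracy",
    "f1",
    "sensitivity",
    "specificity",
)
REGRESSION_METRICS = ("rmse", "mae", "r2")


def _positive_mask(labels: Sequence, pos_label=None) -> np.ndarray:
    labels = np.array([str(v) for v in labels], dtype=object)
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise DataError("AUROC undefined: labels contain a single class")
    if len(levels) > 2 and pos_label is None:
        raise DataError("AUROC on >2 classes requires an explicit pos_label")
    pos = str(pos_label) if pos_label is not None else levels[1]
    if pos not in levels:
        raise DataError(f"positive label {pos!r} not present in labels")
    return labels == pos


def roc_points(scores: Sequence[float], labels: Sequence, pos_label=None) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) from a grouped threshold sweep.

    Points start at (0, 0) and end at (1, 1) with non-decreasing coordinates;
    tied scores contribute a single point (no per-sample interpolation).
    """
    y = _positive_mask(labels, pos_label)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise DataError("scores and labels must have equal length")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    last_of_tie = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[last_of_tie]
    fp = np.cumsum(~y_sorted)[last_of_tie]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    return pd.DataFrame(
        {
            "fpr": np.r_[0.0, fp / n_neg],
            "tpr": np.r_[0.0, tp / n_pos],
            "threshold": np.r_[np.inf, s_sorted[last_of_tie]],
        }
    )


def auroc(scores: Sequence[float], labels: Sequence, pos_label=None) -> float:
    """Area under the ROC curve (trapezoidal; ties counted one half)."""
    pts = roc_points(scores, labels, pos_label)
    return float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))


def prc_points(scores: Sequence[float], labels: Sequence, pos_label=None) -> pd.DataFrame:
    """Precision-recall curve points (recall, precision, threshold)."""
    y = _positive_mask(labels, pos_label)
    precision, recall, thresholds = skm.precision_recall_curve(y.astype(int), scores)
    thr = np.r_[thresholds, np.inf]
    return pd.DataFrame({"recall": recall, "precision": precision, "threshold": thr})


def auprc(scores: Sequence[float], labels: Sequence, pos_label=None) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = _positive_mask(labels, pos_label)
    return float(skm.average_precision_score(y.astype(int), scores))


def mean_ovr_auroc(score_matrix: np.ndarray, labels: Sequence, classes: Sequence) -> float:
    """Unweighted mean of one-vs-rest AUROCs over all classes."""
    labels = np.array([str(v) for v in labels], dtype=object)
    aucs = []
    for k, cls in enumerate(classes):
        y = labels == str(cls)
        if y.all() or not y.any():
            continue
        aucs.append(auroc(score_matrix[:, k], y.astype(int), pos_label=1))
    if not aucs:
        raise DataError("AUROC undefined: test set has a single class")
    return float(np.mean(aucs))


@dataclass
class PerformanceReport:
    """Held-out metrics plus ROC/PRC curve data for plotting."""

    metrics: Dict[str, float]
    n_test: int
    positive_class: Optional[str] = None
    roc: Optional[pd.DataFrame] = None
    prc: Optional[pd.DataFrame] = None

    def to_row(self, **extra) -> dict:
        row = dict(extra)
        row.update({k: float(v) for k, v in self.metrics.items()})
        row["n_test"] = self.n_test
        if self.positive_class is not None:
            row["positive_class"] = self.positive_class
        return row


def calc_performance(model_handle, test, outcome_kind: str) -> PerformanceReport:
    """Evaluate a fitted model on a held-out set.

    ``test`` is a :class:`~tabml.core_data.Dataset` subset; only the model
    handle's score/prediction contracts are used.  Metrics that do not apply
    to the outcome kind are omitted with a warning rather than failing.
    """
    X = test.features
    y = test.outcome.to_numpy()
    if len(X) == 0:
        raise DataError("test set is empty")

    if outcome_kind == "continuous":
        pred = model_handle.predict(X)
        yf = np.asarray(y, dtype=float)
        out = {
            "rmse": float(np.sqrt(skm.mean_squared_error(yf, pred))),
            "mae": float(skm.mean_absolute_error(yf, pred)),
            "r2": float(skm.r2_score(yf, pred)),
        }
        return PerformanceReport(metrics=out, n_test=len(X))

    y_str = np.array([str(v) for v in y], dtype=object)
    pred = np.array([str(v) for v in model_handle.predict(X)], dtype=object)
    out = {
        "accuracy": float(skm.accuracy_score(y_str, pred)),
        "balanced_accuracy": float(skm.balanced_accuracy_score(y_str, pred)),
    }

    if outcome_kind == "binary":
        pos = str(model_handle.positive_class)
        scores = model_handle.positive_score(X)
        thresh_pred = np.where(
            scores >= 0.5, pos, [c for c in model_handle.classes if c != pos][0]
        )
        y_bin = (y_str == pos).astype(int)
        p_bin = (thresh_pred == pos).astype(int)
        out["accuracy"] = float(skm.accuracy_score(y_bin, p_bin))
        out["balanced_accuracy"] = float(skm.balanced_accuracy_score(y_bin, p_bin))
        out["f1"] = float(skm.f1_score(y_bin, p_bin, zero_division=0))
        out["sensitivity"] = float(skm.recall_score(y_bin, p_bin, zero_division=0))
        out["specificity"] = float(skm.recall_score(1 - y_bin, 1 - p_bin, zero_division=0))
        try:
            out["auroc"] = auroc(scores, y_str, pos_label=pos)
            out["auprc"] = auprc(scores, y_str, pos_label=pos)
            roc = roc_points(scores, y_str, pos_label=pos)
            prc = prc_points(scores, y_str, pos_label=pos)
        except DataError as exc:
            warnings.warn(f"omitting AUROC/AUPRC: {exc}")
            roc = prc = None
        return PerformanceReport(
            metrics=out, n_test=len(X), positive_class=pos, roc=roc, prc=prc
        )

    # multiclass
    out["f1"] = float(skm.f1_score(y_str, pred, average="macro", zero_division=0))
    try:
        out["auroc"] = mean_ovr_auroc(model_handle.score_matrix(X), y_str, model_handle.classes)
    except DataError as exc:
        warnings.warn(f"omitting multiclass AUROC: {exc}")
    return PerformanceReport(metrics=out, n_test=len(X))


def compute_metric(name: str, model_handle, X: pd.DataFrame, y, outcome_kind: str) -> float:
    """Compute one named metric from a model handle's contracts.

    Used by hyperparameter tuning and permutation importance so that both
    score models through exactly the same path as final evaluation.
    """
    if name not in GREATER_IS_BETTER:
        raise DataError(f"unknown metric {name!r}; known: {sorted(GREATER_IS_BETTER)}")
    if outcome_kind == "continuous":
        if name not in REGRESSION_METRICS:
            raise DataError(f"metric {name!r} is undefined for continuous outcomes")
        yf = np.asarray(y, dtype=float)
        pred = model_handle.predict(X)
        if name == "rmse":
            return float(np.sqrt(skm.mean_squared_error(yf, pred)))
        if name == "mae":
            return float(skm.mean_absolute_error(yf, pred))
        return float(skm.r2_score(yf, pred))

    if name in REGRESSION_METRICS:
        raise DataError(f"metric {name!r} is undefined for classification outcomes")
    y_str = np.array([str(v) for v in y], dtype=object)
    if outcome_kind == "multiclass" and name == "auroc":
        return mean_ovr_auroc(model_handle.score_matrix(X), y_str, model_handle.classes)
    if name == "auroc":
        return auroc(model_handle.positive_score(X), y_str, pos_label=model_handle.positive_class)
    if name == "auprc":
        return auprc(model_handle.positive_score(X), y_str, pos_label=model_handle.positive_class)
    pred = np.array([str(v) for v in model_handle.predict(X)], dtype=object)
    if name == "accuracy":
        return float(skm.accuracy_score(y_str, pred))
    if name == "balanced_accuracy":
        return float(skm.balanced_accuracy_score(y_str, pred))
    pos = str(model_handle.positive_class)
    y_bin = (y_str == pos).astype(int)
    p_bin = (pred == pos).astype(int)
    if name == "f1":
        return float(skm.f1_score(y_bin, p_bin, zero_division=0))
    if name == "sensitivity":
        return float(skm.recall_score(y_bin, p_bin, zero_division=0))
    return float(skm.recall_score(1 - y_bin, 1 - p_bin, zero_division=0))
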