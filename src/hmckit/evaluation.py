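"""Confusion-matrix construction and classification metrics.

The metric bundle matches the standard evaluation protocol for binary
modification-site predictors: accuracy, sensitivity (recall), precision,
specificity, F1, Matthews correlation coefficient, and ROC-AUC, plus
probability-error metrics (MSE/MAE/RMSE/log-loss).

Zero-denominator cases (e.g. MCC with an empty margin, precision with no
positive predictions) return 0.0 and record the metric name in
``MetricsReport.degenerate`` rather than raising — the common convention for
undefined ratios in this literature.

AUC uses the rank (Mann-Whitney) formulation: the probability that a random
positive outscores a random negative, with ties counting one half. This is
exact and tie-robust, and coincides with trapezoidal ROC integration on
tie-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of the 2x2 cross-tabulation; positive class = 5hmC."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """The metric bundle; all unitless. ``degenerate`` lists metrics whose
    denominator was zero (value reported as 0)."""

    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    mcc: float
    auc: float = float("nan")
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.accuracy,
            "SN": self.sensitivity,
            "Precision": self.precision,
            "SPE": self.specificity,
            "F1": self.f1,
            "MCC": self.mcc,
            "AUC": self.auc,
        }


@dataclass
class ErrorReport:
    """Probability-error metrics against 0/1 labels."""

    mse: float
    mae: float
    rmse: float
    log_loss: float
    mean_average_loss: float  # alias of MAE; see docs/methods.md


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix from binary vectors."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, auc: float = float("nan")) -> MetricsReport:
    """Compute accuracy, SN, precision, SPE, F1 and MCC from counts.

    AUC is threshold-free and cannot be derived from a confusion matrix;
    pass it in from :func:`roc_auc` when scores are available.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = float(cm.TP), float(cm.FP), float(cm.TN), float(cm.FN)
    deg: list[str] = []
    acc = (tp + tn) / cm.n
    sn = _ratio(tp, tp + fn, "sensitivity", deg)
    prec = _ratio(tp, tp + fp, "precision", deg)
    spe = _ratio(tn, tn + fp, "specificity", deg)
    f1 = _ratio(2 * prec * sn, prec + sn, "f1", deg)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", deg)
    return MetricsReport(
        accuracy=acc, sensitivity=sn, precision=prec, specificity=spe,
        f1=f1, mcc=mcc, auc=auc, degenerate=deg,
    )


def roc_auc(y_true, scores) -> float:
    """AUC as the Mann-Whitney probability P(score+ > score-), ties = 1/2."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def error_metrics(y_true, probabilities) -> ErrorReport:
    """MSE/MAE/RMSE/log-loss of predicted probabilities against 0/1 labels.

    Log-loss clips probabilities at 1e-15 from both ends. ``mean_average_loss``
    is reported as an alias of MAE.
    """
    y = _check_binary(y_true, "y_true").astype(float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    err = p - y
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    pc = np.clip(p, 1e-15, 1 - 1e-15)
    ll = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    return ErrorReport(
        mse=mse, mae=mae, rmse=math.sqrt(mse), log_loss=ll, mean_average_loss=mae
    )
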