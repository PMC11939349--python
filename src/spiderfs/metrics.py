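"""Confusion-matrix bookkeeping and the classification metric panel.

All metrics derive from four counts: true/false positives and
true/false negatives, with the minority class coded +1 as the positive
class throughout the package.  Rates are reported as percentages
rounded to two decimals; ratios with a zero denominator are reported as
0 together with a ``degenerate`` flag rather than NaN, so downstream
aggregation over cross-validation folds stays numeric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve


class MetricsError(ValueError):
    """Raised on invalid inputs to metric computations."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a binary confusion matrix (+1 is the positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise MetricsError(f"negative count for {name}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient on the [-1, 1] scale.

        A zero denominator (any margin of the confusion table empty)
        yields 0 by convention.
        """
        num = self.tp * self.tn - self.fp * self.fn
        den = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if den == 0:
            return 0.0
        return num / math.sqrt(den)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count agreement between truth and prediction, +1 positive.

    Both vectors must use the package's {+1, -1} label coding.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricsError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    pos = y_true == 1
    pred_pos = y_pred == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


@dataclass(frozen=True)
class MetricPanel:
    """Percent-scale classification metrics, two-decimal rounded.

    ``mcc`` is the Matthews coefficient scaled to percent (range
    [-100, 100]).  ``degenerate`` names the metrics whose defining
    ratio had a zero denominator and were reported as 0.
    """

    accuracy: float
    misclassification: float
    precision: float
    recall: float
    specificity: float
    f1: float
    false_negative_rate: float
    false_positive_rate: float
    mcc: float
    degenerate: tuple[str, ...]

    #: serialization order mirroring the benchmark report columns
    FIELD_ORDER = (
        "accuracy",
        "misclassification",
        "precision",
        "recall",
        "f1",
        "specificity",
        "false_negative_rate",
        "false_positive_rate",
        "mcc",
    )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self.FIELD_ORDER}
        d["degenerate"] = list(self.degenerate)
        return d


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricPanel:
    """Full metric panel from confusion counts.

    Specificity uses tn/(tn+fp) and the false-positive rate
    fp/(fp+tn); together with recall tp/(tp+fn) and the false-negative
    rate fn/(tp+fn) the complement identities Rcl+FNR = Spe+FPR = 100%
    hold whenever the denominators are non-zero.
    """
    if c.total == 0:
        raise MetricsError("empty confusion counts")
    deg: list[str] = []
    acc = (c.tp + c.tn) / c.total
    pre = _ratio(c.tp, c.tp + c.fp, "precision", deg)
    rcl = _ratio(c.tp, c.tp + c.fn, "recall", deg)
    spe = _ratio(c.tn, c.tn + c.fp, "specificity", deg)
    fnr = _ratio(c.fn, c.tp + c.fn, "false_negative_rate", deg)
    fpr = _ratio(c.fp, c.fp + c.tn, "false_positive_rate", deg)
    if pre + rcl > 0:
        f1 = 2 * pre * rcl / (pre + rcl)
    else:
        deg.append("f1")
        f1 = 0.0
    mcc = c.mcc
    if mcc == 0.0 and min(c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn) == 0:
        deg.append("mcc")

    def pct(x: float) -> float:
        return round(100.0 * x, 2)

    return MetricPanel(
        accuracy=pct(acc),
        misclassification=pct(1.0 - acc),
        precision=pct(pre),
        recall=pct(rcl),
        specificity=pct(spe),
        f1=pct(f1),
        false_negative_rate=pct(fnr),
        false_positive_rate=pct(fpr),
        mcc=pct(mcc),
        degenerate=tuple(deg),
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC staircase as an array of (false-positive rate, recall) pairs.

    Thresholds are taken at the unique score values; the curve runs
    from (0, 0) to (1, 1).  Truth must contain both classes.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise MetricsError("length mismatch between truth and scores")
    if not np.all(np.isfinite(scores)):
        raise MetricsError("non-finite scores")
    if len(np.unique(y_true)) < 2:
        raise MetricsError("ROC undefined for single-class truth")
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    return np.column_stack([fpr, tpr])
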