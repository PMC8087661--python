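"""Confusion matrices and the five classification performance metrics.

Accuracy, recall (sensitivity), precision, specificity and the F2 score
(F-beta with beta = 2, weighting recall over precision) are computed from a
single pooled confusion matrix with the patient class positive. Display
values are rounded to two decimals with round-to-nearest on the double,
matching how the metrics are conventionally printed.

`reconstruct_confusion` inverts the rounding: given 2-dp recall and
specificity plus the group sizes, it searches all integer confusion matrices
for those that reproduce the printed values — useful for turning published
metric tables back into exact integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np


def display_round(x: float | Fraction, ndigits: int = 2) -> float:
    """Round for display: nearest representable double at `ndigits` decimals."""
    return round(float(x), ndigits)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Exact metric values plus 2-dp display values and degeneracy flags."""

    accuracy: float
    recall: float
    precision: float
    specificity: float
    f2: float
    confusion: ConfusionMatrix
    undefined: tuple[str, ...] = ()

    @property
    def display(self) -> dict[str, float]:
        return {
            "accuracy": display_round(self.accuracy),
            "recall": display_round(self.recall),
            "precision": display_round(self.precision),
            "specificity": display_round(self.specificity),
            "F2": display_round(self.f2),
        }

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "specificity": self.specificity,
            "F2": self.f2,
        }


def confusion_from_predictions(predictions, labels) -> ConfusionMatrix:
    """Standard 2x2 counts with the patient class (label 1) positive."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if set(np.unique(predictions)) - {0, 1} or set(np.unique(labels)) - {0, 1}:
        raise ValueError("predictions and labels must be binary 0/1")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five metrics from exact integer counts.

    accuracy = (TP+TN)/N, recall = TP/(TP+FN), precision = TP/(TP+FP),
    specificity = TN/(TN+FP), F2 = 5PR/(4P+R) on exact fractions. A metric
    whose denominator is zero is reported as 0 and listed in ``undefined``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num: int, den: int, name: str) -> Fraction:
        if den == 0:
            undefined.append(name)
            return Fraction(0)
        return Fraction(num, den)

    accuracy = Fraction(cm.tp + cm.tn, cm.total)
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if 4 * precision + recall > 0:
        f2 = 5 * precision * recall / (4 * precision + recall)
    else:
        undefined.append("F2")
        f2 = Fraction(0)
    return MetricsReport(
        accuracy=float(accuracy),
        recall=float(recall),
        precision=float(precision),
        specificity=float(specificity),
        f2=float(f2),
        confusion=cm,
        undefined=tuple(undefined),
    )


def reconstruct_confusion(
    recall_2dp: float, specificity_2dp: float, n_pos: int, n_neg: int
) -> list[ConfusionMatrix]:
    """All integer confusion matrices whose recall/specificity print as given.

    Exhaustive search over TP in 0..n_pos, TN in 0..n_neg. Returns a list:
    one element when the printed pair pins the matrix down uniquely, several
    when ambiguous, empty when no integer matrix rounds to the inputs.
    """
    if not (0 <= recall_2dp <= 1 and 0 <= specificity_2dp <= 1):
        raise ValueError("recall and specificity must be in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    out = []
    for tp in range(n_pos + 1):
        if display_round(Fraction(tp, n_pos)) != display_round(recall_2dp):
            continue
        for tn in range(n_neg + 1):
            if display_round(Fraction(tn, n_neg)) != display_round(specificity_2dp):
                continue
            out.append(ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp))
    return out
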