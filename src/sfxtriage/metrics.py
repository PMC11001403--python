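"""Binary confusion matrix and classification report.

The positive class is "good" (a usable diffraction frame).  All rates are
stored as fractions in [0, 1] and formatted as percentages only when
rendered, matching how such tables are conventionally printed.  Ratios
with a zero denominator (no predicted positives, no actual negatives,
...) are reported as explicitly undefined — never silently zero — because
a model that predicts a single class should look broken, not precise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .labels import BAD, GOOD

__all__ = ["ConfusionMatrix", "ClassificationReport", "MetricsError",
           "confusion_matrix", "classification_report"]


class MetricsError(ValueError):
    """Invalid evaluation input (length mismatch, non-binary labels)."""


def _validate(y_true: Sequence[str], y_pred: Sequence[str]) -> None:
    if len(y_true) != len(y_pred):
        raise MetricsError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise MetricsError("cannot evaluate empty label sequences")
    bad_vals = {v for v in (*y_true, *y_pred) if v not in (GOOD, BAD)}
    if bad_vals:
        raise MetricsError(
            f"labels must be {GOOD!r}/{BAD!r}; found {sorted(bad_vals)}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with positive = good."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self):
        """2x2 layout [[TP, FN], [FP, TN]] (rows = actual good/bad)."""
        return [[self.tp, self.fn], [self.fp, self.tn]]

    def plot(self, ax=None):
        """2x2 heat map with count annotations (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        arr = [[self.tp, self.fn], [self.fp, self.tn]]
        ax.imshow(arr, cmap="Blues")
        for i in range(2):
            for j in range(2):
                ax.text(j, i, str(arr[i][j]), ha="center", va="center")
        ax.set_xticks([0, 1], ["pred good", "pred bad"])
        ax.set_yticks([0, 1], ["actual good", "actual bad"])
        return ax

    def to_text(self) -> str:
        rows = [
            ("", "pred good", "pred bad"),
            ("actual good", str(self.tp), str(self.fn)),
            ("actual bad", str(self.fp), str(self.tn)),
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        return "\n".join("  ".join(c.rjust(w) for c, w in zip(r, widths))
                         for r in rows)


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN over paired true/predicted good-bad labels."""
    _validate(y_true, y_pred)
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == GOOD:
            if p == GOOD:
                tp += 1
            else:
                fn += 1
        else:
            if p == BAD:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    """num/den, or NaN when the denominator is zero (undefined)."""
    return num / den if den else math.nan


@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy, misclassification rate, and per-class P/R/F1/support.

    Per-class misclassification (1 - recall) is the rate at which frames
    of that actual class are sorted into the other one.  ``undefined``
    names the fields whose denominator was zero; those fields are NaN.
    """

    matrix: ConfusionMatrix
    accuracy: float
    misclassification_rate: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    undefined: frozenset[str] = field(default_factory=frozenset)

    @property
    def per_class_misclassification(self) -> dict[str, float]:
        return {cls: 1.0 - r if math.isfinite(r) else math.nan
                for cls, r in self.recall.items()}

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": {"tp": self.matrix.tp, "tn": self.matrix.tn,
                                 "fp": self.matrix.fp, "fn": self.matrix.fn},
            "accuracy": self.accuracy,
            "misclassification_rate": self.misclassification_rate,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "support": dict(self.support),
            "per_class_misclassification": self.per_class_misclassification,
            "undefined": sorted(self.undefined),
        }

    def to_text(self, percent: bool = True) -> str:
        def fmt(v: float) -> str:
            if not math.isfinite(v):
                return "undef"
            return f"{100 * v:.1f}%" if percent else f"{v:.4f}"

        lines = [self.matrix.to_text(), ""]
        lines.append(f"{'':<6}{'precision':>10}{'recall':>10}{'f1':>10}{'support':>10}")
        for cls in (GOOD, BAD):
            lines.append(f"{cls:<6}{fmt(self.precision[cls]):>10}"
                         f"{fmt(self.recall[cls]):>10}{fmt(self.f1[cls]):>10}"
                         f"{self.support[cls]:>10}")
        lines.append("")
        lines.append(f"accuracy            {fmt(self.accuracy):>10}")
        lines.append(f"misclassification   {fmt(self.misclassification_rate):>10}")
        if self.undefined:
            lines.append(f"undefined fields: {', '.join(sorted(self.undefined))}")
        return "\n".join(lines)


def classification_report(y_true: Sequence[str], y_pred: Sequence[str]
                          ) -> ClassificationReport:
    """Full diagnostic report from paired true/predicted labels.

    accuracy = (TP+TN)/total, misclassification = (FP+FN)/total (their sum
    is 1 by construction); per class, precision = correct predictions of
    the class over all predictions of it, recall = over all actual members
    of it, F1 = harmonic mean of the two, support = actual member count.
    """
    cm = confusion_matrix(y_true, y_pred)
    n = cm.total
    undefined: set[str] = set()

    def tracked_ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            undefined.add(name)
        return _ratio(num, den)

    precision = {GOOD: tracked_ratio("precision.good", cm.tp, cm.tp + cm.fp),
                 BAD: tracked_ratio("precision.bad", cm.tn, cm.tn + cm.fn)}
    recall = {GOOD: tracked_ratio("recall.good", cm.tp, cm.tp + cm.fn),
              BAD: tracked_ratio("recall.bad", cm.tn, cm.tn + cm.fp)}
    f1 = {}
    for cls in (GOOD, BAD):
        p, r = precision[cls], recall[cls]
        if not (math.isfinite(p) and math.isfinite(r)) or p + r == 0:
            undefined.add(f"f1.{cls}")
            f1[cls] = math.nan
        else:
            f1[cls] = 2 * p * r / (p + r)
    support = {GOOD: cm.tp + cm.fn, BAD: cm.tn + cm.fp}
    return ClassificationReport(
        matrix=cm,
        accuracy=(cm.tp + cm.tn) / n,
        misclassification_rate=(cm.fp + cm.fn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        undefined=frozenset(undefined),
    )
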