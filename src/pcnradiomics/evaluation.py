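"""Confusion matrices and per-class precision / recall / F1 reporting.

The confusion matrix is oriented rows = predicted class, columns = true
class, with the class order registry carried alongside (IPMN, MCN, SCA by
default, matching the published table layout).  Per class c:

    precision_c = cm[c, c] / row_sum(c)      (predicted-c that are truly c)
    recall_c    = cm[c, c] / col_sum(c)      (true-c that are predicted c)
    F1_c        = 2 * P * R / (P + R)
    OA          = trace / total

A zero denominator yields metric 0 with a flag rather than a silent NaN.
Display rounding is half-up to 4 decimals; internal values are unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics",
           "round_half_up", "DEFAULT_CLASS_ORDER"]

DEFAULT_CLASS_ORDER = ("IPMN", "MCN", "SCA")


def round_half_up(x: float, digits: int = 4) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(10) ** -digits,
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                     # rows predicted x cols true
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise InvalidArgumentError(
                f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


@dataclass
class MetricsReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    overall_accuracy: float
    n: int
    class_order: tuple[str, ...]
    zero_denominator_flags: list[str] = field(default_factory=list)

    def to_dataframe(self, digits: int = 4) -> pd.DataFrame:
        rows = {c: [round_half_up(self.precision[c], digits),
                    round_half_up(self.recall[c], digits),
                    round_half_up(self.f1[c], digits)]
                for c in self.class_order}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["Pre", "Rec", "F1"])


def confusion(true_labels, predicted_labels,
              class_order=DEFAULT_CLASS_ORDER) -> ConfusionMatrix:
    """Tally a predicted x true count matrix."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise InvalidArgumentError("label lists differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise InvalidArgumentError(f"label {t!r}/{p!r} not in class order")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision, recall, F1 and overall accuracy from counts."""
    counts = cm.counts
    if counts.sum() == 0:
        raise InvalidArgumentError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    precision, recall, f1 = {}, {}, {}
    flags = []
    for i, c in enumerate(cm.class_order):
        tp = counts[i, i]
        if row[i] > 0:
            precision[c] = tp / row[i]
        else:
            precision[c] = 0.0
            flags.append(f"precision[{c}]: no predictions")
        if col[i] > 0:
            recall[c] = tp / col[i]
        else:
            recall[c] = 0.0
            flags.append(f"recall[{c}]: no true cases")
        denom = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / denom if denom > 0 else 0.0
    return MetricsReport(
        precision=precision, recall=recall, f1=f1,
        overall_accuracy=float(np.trace(counts) / counts.sum()),
        n=cm.n, class_order=cm.class_order,
        zero_denominator_flags=flags,
    )
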