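"""Binary-classification evaluation: TPR, specificity, FPR, FNR, accuracy.

All five indexes come from a 2x2 confusion table:

    TPR = TP / (TP + FN)        Spe = TN / (TN + FP)
    FPR = FP / (FP + TN)        FNR = FN / (TP + FN)
    Accuracy = (TP + TN) / (TP + TN + FP + FN)

A ratio with a zero denominator is reported as ``None`` (an explicit
"undefined" sentinel), never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

from .errors import InvalidInputError, LengthMismatchError, NotBinaryError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidInputError("invalid input: negative confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def swap_positive(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, fn=self.fp, tn=self.tp, fp=self.fn)


@dataclass(frozen=True)
class MetricsReport:
    tpr: Optional[float]
    spe: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    accuracy: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "tpr": self.tpr, "spe": self.spe, "fpr": self.fpr, "fnr": self.fnr,
            "accuracy": self.accuracy,
            "counts": {"tp": self.counts.tp, "fn": self.counts.fn,
                       "tn": self.counts.tn, "fp": self.counts.fp},
        }


def confusion_counts(predicted: Sequence[Hashable], truth: Sequence[Hashable],
                     positive_label: Hashable) -> ConfusionCounts:
    """Tally the 2x2 table of ``predicted`` vs ``truth`` w.r.t. ``positive_label``."""
    if len(predicted) != len(truth):
        raise LengthMismatchError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if len(truth) == 0:
        raise InvalidInputError("invalid input: empty label lists")
    if len(set(truth)) > 2:
        raise NotBinaryError(f"not binary: {len(set(truth))} distinct truth labels")
    if len(set(predicted)) > 2:
        raise NotBinaryError(f"not binary: {len(set(predicted))} distinct predicted labels")
    tp = fn = tn = fp = 0
    for p, t in zip(predicted, truth):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """All five indexes from one confusion table."""
    if counts.total < 1:
        raise InvalidInputError("invalid input: empty confusion table")
    return MetricsReport(
        tpr=_ratio(counts.tp, counts.tp + counts.fn),
        spe=_ratio(counts.tn, counts.tn + counts.fp),
        fpr=_ratio(counts.fp, counts.fp + counts.tn),
        fnr=_ratio(counts.fn, counts.tp + counts.fn),
        accuracy=(counts.tp + counts.tn) / counts.total,
        counts=counts,
    )


def evaluate(predicted: Sequence[Hashable], truth: Sequence[Hashable],
             positive_label: Hashable) -> MetricsReport:
    return compute_metrics(confusion_counts(predicted, truth, positive_label))
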