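"""Confusion-matrix evaluation and printed-number consistency checks.

The positive class is *abnormal*.  The three reported metrics are

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)

so sensitivity measures how well abnormal recordings are caught and
specificity how well normal recordings are recognized.
:func:`reconstruct_accuracy` recovers an accuracy from per-class rates and
class counts (counts are integers, so the implied TP/TN are rounded to the
nearest integer) — used to cross-check that published rate/count/accuracy
triples are arithmetically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyDatasetError, UndefinedMetricError
from .model import DualPathModel
from .preprocess import SegmentSet


@dataclass
class EvalReport:
    """Confusion counts (abnormal = positive) and the derived percentages."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float

    def confusion_text(self) -> str:
        return (
            "              pred normal  pred abnormal\n"
            f"true normal   {self.tn:11d}  {self.fp:13d}\n"
            f"true abnormal {self.fn:11d}  {self.tp:13d}\n"
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Sensitivity/specificity/accuracy (percent) from confusion counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity")
    total = tp + tn + fp + fn
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / total,
    )


def evaluate(model: DualPathModel, segments: SegmentSet,
             batch: int = 32) -> EvalReport:
    """Per-segment evaluation on original (non-augmented) segments.

    Reversed augmentation segments are excluded: they exist only to enlarge
    the training set.  Predicted class is the softmax argmax; an exact
    0.5/0.5 tie resolves to normal.
    """
    keep = [i for i, p in enumerate(segments.provenance) if p == "original"]
    if not keep:
        raise EmptyDatasetError("no original-provenance segments to evaluate")
    segs = segments.subset(keep)
    y = segs.y
    preds = np.empty(len(segs), dtype=int)
    for i in range(0, len(segs), batch):
        xb = np.ascontiguousarray(
            segs.data[i:i + batch].transpose(0, 2, 1), dtype=model.dtype)
        probs = model.predict_proba(xb)
        # argmax returns the first (normal) index on an exact tie
        preds[i:i + batch] = probs.argmax(axis=1)
    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return compute_metrics(tp, tn, fp, fn)


def reconstruct_accuracy(sensitivity: float, specificity: float,
                         n_pos: int, n_neg: int) -> float:
    """Accuracy implied by per-class rates and integer class counts.

    ``TP = round(sensitivity * n_pos / 100)`` and ``TN = round(specificity *
    n_neg / 100)``; returns ``100 * (TP + TN) / (n_pos + n_neg)``.
    """
    tp = int(round(sensitivity * n_pos / 100.0))
    tn = int(round(specificity * n_neg / 100.0))
    return 100.0 * (tp + tn) / (n_pos + n_neg)
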