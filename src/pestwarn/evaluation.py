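"""Multiclass evaluation: confusion matrix and one-vs-rest metrics.

The confusion matrix is oriented rows = true level, columns = predicted
level.  Each warning level is then scored one-vs-rest: TP/FN/FP/TN,
precision, recall and F1, with full precision kept internally and 2-decimal
rounding applied only for display.  F1 is computed from the unrounded
precision and recall; an ``f1_from_rounded`` variant (F1 of the 2-dp-rounded
p and r) is reported alongside because rounding before F1 can shift the
second decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import json

import numpy as np

from .exceptions import InputError


@dataclass
class LevelMetrics:
    """One-vs-rest counts and metrics for a single warning level."""

    label: str
    tp: int
    fn: int
    fp: int
    tn: int
    precision: float
    recall: float
    f1: float
    f1_from_rounded: float


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-level one-vs-rest metrics."""

    matrix: np.ndarray
    labels: list[str]
    per_level: list[LevelMetrics]
    overall_accuracy: float

    def to_dict(self, digits: int = 2) -> dict:
        return {
            "labels": list(self.labels),
            "matrix": self.matrix.astype(int).tolist(),
            "overall_accuracy": round(float(self.overall_accuracy), 4),
            "per_level": [
                {"label": m.label, "TP": m.tp, "FN": m.fn, "FP": m.fp,
                 "TN": m.tn,
                 "precision": round(m.precision, digits),
                 "recall": round(m.recall, digits),
                 "f1": round(m.f1, digits),
                 "f1_from_rounded": round(m.f1_from_rounded, digits)}
                for m in self.per_level],
        }

    def to_json(self, path, digits: int = 2) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(digits), fh, indent=2)
            fh.write("\n")


def confusion_matrix(true_levels: Sequence[int], predicted_levels: Sequence[int],
                     k: int) -> np.ndarray:
    """Count matrix with entry (i, j) = samples of true level i predicted j.

    Raises
    ------
    InputError
        length mismatch or labels outside 0..k-1.
    """
    t = np.asarray(list(true_levels), dtype=int)
    p = np.asarray(list(predicted_levels), dtype=int)
    if t.shape != p.shape:
        raise InputError(f"length mismatch: {len(t)} vs {len(p)}")
    if len(t) and (((t < 0) | (t >= k)).any() or ((p < 0) | (p >= k)).any()):
        raise InputError(f"labels must lie in 0..{k - 1}")
    m = np.zeros((k, k), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return m


def binary_metrics(tp: int, fn: int, fp: int, tn: int
                   ) -> tuple[float, float, float, float]:
    """Precision, recall, F1 and round-before-F1 from one-vs-rest counts.

    Undefined ratios (zero denominators) are reported as 0.0.
    """
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if precision + recall > 0 else 0.0
    pr, rr = round(precision, 2), round(recall, 2)
    f1r = 2 * pr * rr / (pr + rr) if pr + rr > 0 else 0.0
    _ = tn  # TN does not enter precision/recall/F1
    return precision, recall, f1, f1r


def per_level_metrics(matrix: np.ndarray,
                      labels: Sequence[str] | None = None) -> EvaluationReport:
    """One-vs-rest report from a confusion matrix.

    Raises
    ------
    InputError
        empty or non-square matrix, or negative entries.
    """
    m = np.asarray(matrix, dtype=np.int64)
    if m.size == 0 or m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"confusion matrix must be square and nonempty, "
                         f"got shape {m.shape}")
    if (m < 0).any():
        raise InputError("confusion matrix entries must be nonnegative")
    k = m.shape[0]
    if labels is None:
        from .preprocessing import ROMAN
        labels = ROMAN[:k]
    total = int(m.sum())
    per = []
    for i in range(k):
        tp = int(m[i, i])
        fn = int(m[i, :].sum() - tp)
        fp = int(m[:, i].sum() - tp)
        tn = total - tp - fn - fp
        p, r, f1, f1r = binary_metrics(tp, fn, fp, tn)
        per.append(LevelMetrics(labels[i], tp, fn, fp, tn, p, r, f1, f1r))
    accuracy = float(np.trace(m) / total) if total else 0.0
    return EvaluationReport(matrix=m, labels=list(labels), per_level=per,
                            overall_accuracy=accuracy)


def evaluate_predictions(true_levels: Sequence[int],
                         predicted_levels: Sequence[int], k: int,
                         labels: Sequence[str] | None = None) -> EvaluationReport:
    """Report directly from label pairs (matrix built internally)."""
    return per_level_metrics(confusion_matrix(true_levels, predicted_levels, k),
                             labels)
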