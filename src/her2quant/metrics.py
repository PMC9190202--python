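"""Multiclass evaluation: one-vs-rest confusion counts, the five headline
metrics (accuracy, precision, recall, specificity, F1), and the clinical
4-class to 3-class merge (0/1+ -> Negative, 2+ -> Equivocal, 3+ -> Positive).

Per-class metrics are computed one-vs-rest from TP/FP/TN/FN and averaged
without class weighting (macro). Zero-denominator cases are defined as 0 and
emit a warning, so repeated-split aggregation never propagates NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import SCORE_TO_CLINICAL
from .errors import DataError

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence
) -> np.ndarray:
    """K x K matrix; entry (i, j) counts true class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise DataError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    mat = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise DataError(f"label outside class order: true={t!r} pred={p!r}")
        mat[index[t], index[p]] += 1
    return mat


def counts_from_matrix(mat: np.ndarray) -> list[ConfusionCounts]:
    """Per-class one-vs-rest counts from a confusion matrix."""
    mat = np.asarray(mat)
    total = int(mat.sum())
    counts = []
    for i in range(mat.shape[0]):
        tp = int(mat[i, i])
        fn = int(mat[i].sum()) - tp
        fp = int(mat[:, i].sum()) - tp
        tn = total - tp - fn - fp
        counts.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    return counts


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; defining it as 0", stacklevel=3)
        return 0.0
    return num / den


def class_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five metrics for a single one-vs-rest count set."""
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_div(c.tn, c.fp + c.tn, "specificity")
    accuracy = _safe_div(c.tp + c.tn, c.total, "accuracy")
    if precision > 0 and recall > 0:
        f1 = 2.0 / (1.0 / precision + 1.0 / recall)
    else:
        f1 = _safe_div(0.0, 0.0, "f1") if (c.tp + c.fp + c.fn) else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def compute_metrics(
    counts: Sequence[ConfusionCounts],
    class_names: Sequence[str] | None = None,
) -> dict:
    """Per-class metrics plus unweighted (macro) averages.

    When the counts derive from a single confusion matrix, ``overall_accuracy``
    (trace over total) is also reported.
    """
    names = list(class_names) if class_names is not None else [str(i) for i in range(len(counts))]
    per_class = {name: class_metrics(c) for name, c in zip(names, counts)}
    macro = {
        m: float(np.mean([per_class[name][m] for name in names])) for m in METRIC_NAMES
    }
    result = {"per_class": per_class, "macro": macro}
    total = counts[0].total if counts else 0
    if total and all(c.total == total for c in counts):
        trace = sum(c.tp for c in counts)
        result["overall_accuracy"] = trace / total
    return result


def evaluate(y_true: Sequence, y_pred: Sequence, class_order: Sequence) -> dict:
    """Confusion matrix + metrics in one call."""
    mat = confusion_matrix(y_true, y_pred, class_order)
    out = compute_metrics(counts_from_matrix(mat), class_names=list(class_order))
    out["confusion_matrix"] = mat.tolist()
    out["class_order"] = list(class_order)
    return out


def merge_classes(labels: Sequence, mapping: dict | None = None) -> list:
    """Map 4-class HER2 scores to the clinical 3-class vocabulary.

    The default mapping sends 0 and 1+ to Negative, 2+ to Equivocal and 3+ to
    Positive; ``normal``/``noise`` pass through unchanged. Labels outside the
    mapping raise a data error.
    """
    if mapping is None:
        mapping = {**SCORE_TO_CLINICAL, "normal": "normal", "noise": "noise"}
    out = []
    for lab in labels:
        if lab not in mapping:
            raise DataError(f"label {lab!r} not covered by merge mapping")
        out.append(mapping[lab])
    return out
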