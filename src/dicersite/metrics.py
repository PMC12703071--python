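"""Evaluation metrics for interval-class cleavage-site prediction.

Multi-class metrics: top-1/top-k accuracy, macro F1 (averaged over the
total number of classes NC, so classes absent from a test fold contribute
F1 = 0), weighted F1 (weighted by true-class frequency, so absent classes
carry weight 0), the confusion matrix (rows = true class, columns =
predicted class), and the two positional metrics:

* PMF (perfect match fraction): among samples where both the prediction
  and the label are nonzero ("true positives" in the positional sense),
  the fraction predicted at exactly the correct interval.
* PSE (positional shift error): among the same samples, the mean absolute
  difference |pred - lbl| in interval units.  PMF = 1 iff PSE = 0.

Binary metrics collapse class 0 vs nonzero: accuracy, specificity,
sensitivity and MCC.  A zero MCC denominator is reported as 0 with a flag.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .io_formats import ValidationError
from .model import predict_topk

__all__ = [
    "PredictionSet",
    "EvaluationReport",
    "confusion_matrix",
    "top_k_accuracy",
    "macro_f1",
    "weighted_f1",
    "pmf_pse",
    "binarize",
    "binary_metrics",
    "evaluate",
]


@dataclasses.dataclass
class PredictionSet:
    """Labels, hard predictions and (optionally) full probability rows."""

    labels: np.ndarray
    preds: np.ndarray
    probs: np.ndarray | None
    n_classes: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.preds = np.asarray(self.preds, dtype=np.int64)
        if self.labels.shape != self.preds.shape:
            raise ValidationError("labels and predictions differ in length")
        for name, arr in (("label", self.labels), ("prediction", self.preds)):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_classes):
                raise ValidationError(f"{name} outside {{0..{self.n_classes - 1}}}")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=np.float64)
            if self.probs.shape != (len(self.labels), self.n_classes):
                raise ValidationError("probability matrix shape mismatch")

    @classmethod
    def from_probs(cls, labels: np.ndarray, probs: np.ndarray) -> "PredictionSet":
        probs = np.asarray(probs, dtype=np.float64)
        preds = predict_topk(probs, 1)[:, 0]
        return cls(labels=labels, preds=preds, probs=probs,
                   n_classes=probs.shape[1])

    @property
    def n(self) -> int:
        return len(self.labels)


def confusion_matrix(preds: PredictionSet) -> np.ndarray:
    """Counts[true, predicted] over the full class set."""
    c = preds.n_classes
    mat = np.zeros((c, c), dtype=np.int64)
    np.add.at(mat, (preds.labels, preds.preds), 1)
    return mat


def top_k_accuracy(preds: PredictionSet, k: int = 1) -> float:
    if k == 1:
        return float((preds.preds == preds.labels).mean())
    if preds.probs is None:
        raise ValidationError("top-k accuracy for k > 1 needs probabilities")
    topk = predict_topk(preds.probs, k)
    return float((topk == preds.labels[:, None]).any(axis=1).mean())


def _per_class_f1(mat: np.ndarray) -> np.ndarray:
    tp = np.diag(mat).astype(np.float64)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    return f1


def macro_f1(preds: PredictionSet) -> float:
    """Mean per-class F1 over all NC classes (absent classes count as 0)."""
    return float(_per_class_f1(confusion_matrix(preds)).mean())


def weighted_f1(preds: PredictionSet) -> float:
    """Per-class F1 weighted by true-class frequency."""
    mat = confusion_matrix(preds)
    weights = mat.sum(axis=1) / preds.n
    return float((weights * _per_class_f1(mat)).sum())


def pmf_pse(preds: PredictionSet) -> tuple[float, float]:
    """Positional metrics over samples with pred != 0 and lbl != 0.

    Returns (nan, nan) when no such sample exists — the metrics are
    undefined there, never 0.
    """
    tp_mask = (preds.preds != 0) & (preds.labels != 0)
    n_tp = int(tp_mask.sum())
    if n_tp == 0:
        return math.nan, math.nan
    p, l = preds.preds[tp_mask], preds.labels[tp_mask]
    pmf = float((p == l).mean())
    pse = float(np.abs(p - l).mean())
    return pmf, pse


def binarize(preds: PredictionSet) -> PredictionSet:
    """Collapse to negative (class 0) vs positive (any nonzero class)."""
    return PredictionSet(labels=(preds.labels != 0).astype(np.int64),
                         preds=(preds.preds != 0).astype(np.int64),
                         probs=None, n_classes=2)


def binary_metrics(binary: PredictionSet) -> dict:
    """Acc/Spe/Sen/MCC from the binary confusion counts."""
    if binary.n_classes != 2:
        raise ValidationError("binary metrics require a binarized prediction set")
    lbl, prd = binary.labels, binary.preds
    tp = int(((lbl == 1) & (prd == 1)).sum())
    tn = int(((lbl == 0) & (prd == 0)).sum())
    fp = int(((lbl == 0) & (prd == 1)).sum())
    fn = int(((lbl == 1) & (prd == 0)).sum())
    acc = (tp + tn) / binary.n
    spe = tn / (tn + fp) if (tn + fp) else math.nan
    sen = tp / (tp + fn) if (tp + fn) else math.nan
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc_defined = denom > 0
    mcc = (tp * tn - fp * fn) / denom if mcc_defined else 0.0
    return {"acc": acc, "spe": spe, "sen": sen, "mcc": mcc,
            "mcc_defined": mcc_defined,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


@dataclasses.dataclass
class EvaluationReport:
    """All metrics for one prediction set."""

    n: int
    top1: float
    top3: float | None
    macro_f1: float
    weighted_f1: float
    pmf: float
    pse: float
    binary: dict
    confusion: np.ndarray

    METRIC_KEYS = ("top1", "top3", "macro_f1", "weighted_f1", "pmf", "pse")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "top1": self.top1,
            "top3": self.top3,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "pmf": self.pmf,
            "pse": self.pse,
            "binary": self.binary,
            "confusion": self.confusion.tolist(),
        }

    def save(self, path: str | Path) -> None:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            return x
        Path(path).write_text(json.dumps(clean(self.to_dict()), indent=1))

    def confusion_to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")


def evaluate(preds: PredictionSet) -> EvaluationReport:
    pmf, pse = pmf_pse(preds)
    top3 = None
    if preds.probs is not None:
        top3 = top_k_accuracy(preds, min(3, preds.n_classes))
    return EvaluationReport(
        n=preds.n,
        top1=top_k_accuracy(preds, 1),
        top3=top3,
        macro_f1=macro_f1(preds),
        weighted_f1=weighted_f1(preds),
        pmf=pmf,
        pse=pse,
        binary=binary_metrics(binarize(preds)),
        confusion=confusion_matrix(preds),
    )
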