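"""Classification metrics: confusion matrix, macro P/R/F1, and two AUC modes.

The two AUC summaries are (a) the unweighted mean of per-class one-vs-rest
AUCs (classes lacking positives or negatives are excluded with a warning)
and (b) a single "binarized" AUC obtained by flattening every (cell,
class) pair into one one-vs-rest indicator/score list (micro averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .data import ValidationError


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    per_class_auc: dict[str, float] = field(default_factory=dict)
    mean_auc: float = float("nan")
    binary_auc: float = float("nan")
    vocabulary: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_auc": self.mean_auc,
            "binary_auc": self.binary_auc,
            "per_class_auc": dict(self.per_class_auc),
            "vocabulary": list(self.vocabulary),
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(y_true, y_pred, vocabulary: list[str]) -> np.ndarray:
    """C x C counts; entry (i, j) = true class i predicted as class j."""
    vocab = list(vocabulary)
    unknown = set(y_true) | set(y_pred)
    unknown -= set(vocab)
    if unknown:
        raise ValidationError(f"labels outside the vocabulary: {sorted(unknown)}")
    return skm.confusion_matrix(y_true, y_pred, labels=vocab)


def classification_metrics(confusion: np.ndarray,
                           average: str = "macro") -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) from a confusion matrix.

    Per-class precision = diag/column-sum and recall = diag/row-sum, with
    0 substituted (and a warning) when a denominator is zero; macro
    averaging by default, ``average="weighted"`` weights by class support.
    """
    confusion = np.asarray(confusion, dtype=np.float64)
    total = confusion.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    diag = np.diag(confusion)
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        warnings.warn("some classes have no predictions or no support; "
                      "their precision/recall is taken as 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / np.maximum(precision + recall, 1e-300),
                      0.0)
    if average == "weighted":
        w = row / total
    elif average == "macro":
        w = np.full(len(diag), 1.0 / len(diag))
    else:
        raise ValidationError(f"unknown averaging mode {average!r}")
    return (
        float(diag.sum() / total),
        float((precision * w).sum()),
        float((recall * w).sum()),
        float((f1 * w).sum()),
    )


def roc_auc(y_true, scores: np.ndarray,
            vocabulary: list[str]) -> tuple[dict[str, float], float, float]:
    """One-vs-rest AUC per class, their unweighted mean, and the micro AUC.

    ``scores`` holds one row of class probabilities per cell, columns in
    vocabulary order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    vocab = list(vocabulary)
    if scores.shape != (len(y_true), len(vocab)):
        raise ValidationError(
            f"scores shape {scores.shape} does not match "
            f"{len(y_true)} cells x {len(vocab)} classes")
    y_idx = np.array([vocab.index(l) for l in y_true])
    per_class: dict[str, float] = {}
    for c, name in enumerate(vocab):
        pos = y_idx == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {name!r} has no positives or no negatives; "
                          "excluded from the mean AUC", stacklevel=2)
            continue
        per_class[name] = float(skm.roc_auc_score(pos, scores[:, c]))
    mean_auc = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    onehot = np.zeros_like(scores)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    binary_auc = float(skm.roc_auc_score(onehot.ravel(), scores.ravel()))
    return per_class, mean_auc, binary_auc


def evaluate_predictions(y_true, scores: np.ndarray, vocabulary: list[str],
                         average: str = "macro") -> EvaluationReport:
    """Full report from true labels and per-cell class probabilities."""
    vocab = list(vocabulary)
    y_pred = [vocab[i] for i in np.asarray(scores).argmax(axis=1)]
    conf = confusion_matrix(y_true, y_pred, vocab)
    acc, prec, rec, f1 = classification_metrics(conf, average=average)
    per_class, mean_auc, binary_auc = roc_auc(y_true, scores, vocab)
    return EvaluationReport(
        accuracy=acc, precision=prec, recall=rec, f1=f1, confusion=conf,
        per_class_auc=per_class, mean_auc=mean_auc, binary_auc=binary_auc,
        vocabulary=vocab,
    )
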