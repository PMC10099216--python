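"""Confusion matrices and classification performance measures.

Accuracy is the trace fraction of the confusion matrix (the multi-class
form of (TP+TN)/(TP+TN+FP+FN)); precision, recall and F1 are computed
one-vs-rest per class, with F1 = 2·P·R/(P+R).  The summary F1 is the
unweighted (macro) mean over classes — the reading that measures how
evenly accuracy is distributed across categories.  Undefined ratios
(empty denominators) are set to 0 with a logged warning so every report
is total and deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "confusion", "summarize"]


@dataclass(frozen=True)
class EvaluationReport:
    task: str
    n_classes: int
    class_names: tuple[str, ...]
    confusion: np.ndarray  # rows = truth, columns = prediction
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    n_evaluated: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_classes": self.n_classes,
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "n_evaluated": self.n_evaluated,
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def render_table(self) -> str:
        """Confusion matrix as counts with row-normalised percentages."""
        names = self.class_names or tuple(str(i) for i in range(self.n_classes))
        width = max(10, max(len(n) for n in names) + 2)
        header = "truth\\pred".ljust(width) + "".join(n.rjust(width) for n in names)
        lines = [header]
        totals = self.confusion.sum(axis=1)
        for i, name in enumerate(names):
            row = name.ljust(width)
            for j in range(self.n_classes):
                pct = 100.0 * self.confusion[i, j] / totals[i] if totals[i] else 0.0
                row += f"{self.confusion[i, j]:d} ({pct:.0f}%)".rjust(width)
            lines.append(row)
        lines.append(f"accuracy: {self.accuracy:.4f}  macro-F1: {self.macro_f1:.4f}")
        return "\n".join(lines)


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K×K counts: entry (a, b) = windows of true class a predicted as b.

    Labels are 0-based class indices in [0, n_classes).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"y_true and y_pred differ in length: {y_true.size} vs {y_pred.size}"
        )
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def summarize(
    conf: np.ndarray,
    task: str = "stage",
    class_names: tuple[str, ...] | None = None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from a confusion matrix."""
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {conf.shape}")
    if (conf < 0).any():
        raise ValueError("confusion matrix entries must be >= 0")
    total = int(conf.sum())
    if total == 0:
        raise ValueError("confusion matrix is all-zero; nothing was evaluated")
    k = conf.shape[0]
    names = class_names or tuple(str(i) for i in range(k))
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    precision = np.zeros(k)
    recall = np.zeros(k)
    for c in range(k):
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c])
        else:
            logger.warning("class %s: precision undefined (no predictions); set to 0",
                           names[c])
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c])
        else:
            logger.warning("class %s: recall undefined (no true samples); set to 0",
                           names[c])
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return EvaluationReport(
        task=task,
        n_classes=k,
        class_names=names,
        confusion=conf.astype(int),
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
        n_evaluated=total,
    )
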