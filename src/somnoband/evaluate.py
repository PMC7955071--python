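"""Performance battery: confusion matrix, recall/precision/F1, Cohen's kappa.

All metrics derive from a single C x C confusion matrix with rows = true
class and columns = predicted class.  Per-class recall, precision and F1
use the one-vs-rest reduction; kappa is the chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),

with p_o the overall accuracy (trace / N) and p_e the expected chance
agreement from the row and column marginals, p_e = sum_c a_c b_c / N^2.
Degenerate 0/0 ratios are reported as 0 with a warning so that
cross-validation folds missing a class do not crash aggregation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import LABELS

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "prf",
    "kappa",
    "metric_set",
    "EvaluationReport",
]

#: Fixed class order for the apnea problem.
CLASS_ORDER: tuple[str, ...] = LABELS  # (OSA, CSA, NB)


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square and match classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Per-true-class rates; rows with no samples stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out


def _resolve_classes(y_true, y_pred, classes) -> tuple[str, ...]:
    if classes is not None:
        return tuple(classes)
    seen = set(map(str, y_true)) | set(map(str, y_pred))
    if seen <= set(CLASS_ORDER):
        return CLASS_ORDER
    return tuple(sorted(seen))


def confusion(y_true, y_pred, classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Confusion matrix with a fixed class order (OSA, CSA, NB by default)."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = _resolve_classes(y_true, y_pred, classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def prf(cm: ConfusionMatrix, class_index: int) -> tuple[float, float, float]:
    """(recall, precision, F1) for one class, one-vs-rest.

    recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2*precision*recall/(precision+recall); 0/0 -> 0 with a warning.
    """
    tp = cm.counts[class_index, class_index]
    fn = cm.counts[class_index].sum() - tp
    fp = cm.counts[:, class_index].sum() - tp

    def _ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            warnings.warn(
                f"degenerate class {cm.classes[class_index]!r}: {what} is 0/0, "
                "reporting 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return 0.0
        return num / den

    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return float(recall), float(precision), float(f1)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the confusion-matrix marginals."""
    n = cm.n
    if n < 1:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    a = cm.counts.sum(axis=1)  # true-class marginals
    b = cm.counts.sum(axis=0)  # predicted-class marginals
    p_e = float(a @ b) / (n * n)
    if p_e == 1.0:
        raise ValueError("chance agreement p_e = 1; kappa undefined "
                         "(all mass in one row/column cell)")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class MetricSet:
    """Per-class and macro-averaged metrics plus accuracy and kappa."""

    classes: tuple[str, ...]
    recall: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    macro_recall: float
    macro_precision: float
    macro_f1: float
    accuracy: float
    kappa: float


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """Compute the full metric battery from one confusion matrix."""
    rec, pre, f1 = {}, {}, {}
    for i, c in enumerate(cm.classes):
        r, p, f = prf(cm, i)
        rec[c], pre[c], f1[c] = r, p, f
    return MetricSet(
        classes=cm.classes,
        recall=rec,
        precision=pre,
        f1=f1,
        macro_recall=float(np.mean(list(rec.values()))),
        macro_precision=float(np.mean(list(pre.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        accuracy=float(np.trace(cm.counts) / cm.n),
        kappa=kappa(cm),
    )


@dataclass
class EvaluationReport:
    """Cross-validation evaluation artifact, JSON round-trippable."""

    classifier: str
    classes: tuple[str, ...]
    fold_matrices: list[np.ndarray]
    averaged_matrix: np.ndarray  # mean of row-normalized per-fold matrices
    total_counts: np.ndarray  # element-wise sum of fold counts
    fold_accuracies: list[float]
    mean_accuracy: float
    metrics: MetricSet  # from the pooled counts
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier,
            "classes": list(self.classes),
            "fold_matrices": [m.tolist() for m in self.fold_matrices],
            "averaged_matrix": self.averaged_matrix.tolist(),
            "total_counts": self.total_counts.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "metrics": asdict(self.metrics),
            "config": self.config,
        }
        d["metrics"]["classes"] = list(self.metrics.classes)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        m = d["metrics"]
        m["classes"] = tuple(m["classes"])
        return cls(
            classifier=d["classifier"],
            classes=tuple(d["classes"]),
            fold_matrices=[np.asarray(x) for x in d["fold_matrices"]],
            averaged_matrix=np.asarray(d["averaged_matrix"]),
            total_counts=np.asarray(d["total_counts"]),
            fold_accuracies=d["fold_accuracies"],
            mean_accuracy=d["mean_accuracy"],
            metrics=MetricSet(**m),
            config=d.get("config", {}),
        )
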