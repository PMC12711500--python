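"""Confusion matrix, classification metrics, one-vs-rest ROC/AUC and the
ablation accounting table.

Definitions (K classes, one-vs-rest marginalization of the K x K count
grid with rows = true class, columns = predicted class):

    precision_c = TP_c / (TP_c + FP_c)
    recall_c    = TP_c / (TP_c + FN_c)          (= TPR, sensitivity)
    F1_c        = 2 P R / (P + R)
    accuracy    = trace / total

"Per-class accuracy" is reported as per-class recall — the number of a
class's samples the model got right over that class's test size — which
is the reading under which a per-class table is consistent with
per-class false-negative counts.  A one-vs-rest binary-accuracy variant
((TP + TN) / total per class) is available behind a flag.

0/0 ratios (e.g. precision of a never-predicted class) are reported as
0 with a logged warning.  Weighted averages use true-class support.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "MetricsReport",
    "compute_metrics",
    "RocCurve",
    "roc_auc",
    "AblationRow",
    "ablation_report",
]


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    # one-vs-rest marginals
    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fn - self.fp

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + list(self.class_names))
            for name, row in zip(self.class_names, self.counts):
                writer.writerow([name] + [int(v) for v in row])

    def plot(self, path) -> None:
        """Render a heatmap (matplotlib, Agg backend)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(self.counts, cmap="Blues")
        ax.set_xticks(range(self.num_classes), self.class_names, rotation=45, ha="right")
        ax.set_yticks(range(self.num_classes), self.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(self.num_classes):
            for j in range(self.num_classes):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center", fontsize=8)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion_matrix(y_true, y_pred, num_classes: int, class_names=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}")
    if y_true.size and (max(y_true.max(), y_pred.max()) >= num_classes or min(y_true.min(), y_pred.min()) < 0):
        raise ValueError(f"labels out of range [0, {num_classes})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))
    return ConfusionMatrix(counts, list(class_names) if class_names else [])


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    per_class_accuracy: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    class_names: list

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "per_class": {
                name: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "accuracy": float(self.per_class_accuracy[i]),
                    "support": int(self.support[i]),
                }
                for i, name in enumerate(self.class_names)
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [f"{'class':<26}{'prec':>8}{'recall':>8}{'f1':>8}{'acc':>8}{'support':>9}"]
        for i, name in enumerate(self.class_names):
            lines.append(
                f"{name:<26}{self.precision[i]:>8.4f}{self.recall[i]:>8.4f}"
                f"{self.f1[i]:>8.4f}{self.per_class_accuracy[i]:>8.4f}{self.support[i]:>9d}"
            )
        lines.append(
            f"{'weighted avg':<26}{self.weighted_precision:>8.4f}"
            f"{self.weighted_recall:>8.4f}{self.weighted_f1:>8.4f}{'':>8}{int(self.support.sum()):>9d}"
        )
        lines.append(f"overall accuracy: {self.accuracy:.4f}")
        return "\n".join(lines)


def _safe_div(num, den, what: str) -> np.ndarray:
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    zero = den == 0
    if zero.any():
        logger.warning("%s undefined (0/0) for %d class(es); reporting 0", what, int(zero.sum()))
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=~zero)
    return out


def compute_metrics(cm: ConfusionMatrix, per_class_accuracy: str = "recall") -> MetricsReport:
    """All headline metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    if per_class_accuracy == "recall":
        pca = recall
    elif per_class_accuracy == "ovr":
        pca = (cm.tp + cm.tn) / cm.total
    else:
        raise ValueError("per_class_accuracy must be 'recall' or 'ovr'")
    support = cm.support
    weights = support / support.sum()
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=precision,
        recall=recall,
        f1=f1,
        per_class_accuracy=np.asarray(pca, dtype=np.float64),
        support=support,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((weights * precision).sum()),
        weighted_recall=float((weights * recall).sum()),
        weighted_f1=float((weights * f1).sum()),
        class_names=cm.class_names,
    )


@dataclass
class RocCurve:
    """One-vs-rest ROC sweeps and AUCs per class."""

    fpr: dict  # class index -> array
    tpr: dict
    auc: dict  # class index -> float (absent classes are missing)
    macro_auc: float
    missing: list

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "fpr", "tpr"])
            for c in sorted(self.fpr):
                for f, t in zip(self.fpr[c], self.tpr[c]):
                    writer.writerow([c, f, t])


def roc_auc(scores, y_true, num_classes: int | None = None, validate: bool = True) -> RocCurve:
    """One-vs-rest ROC over all distinct score thresholds (ties grouped),
    AUC by trapezoidal integration, macro average over defined classes.

    ``validate=False`` skips the probability-row check, allowing sweeps
    over raw (monotonically transformed) scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be (n_samples, n_classes) aligned with y_true")
    row_sums = scores.sum(axis=1)
    if validate and scores.size and not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1 within 1e-6")
    K = num_classes or scores.shape[1]
    fpr, tpr, auc, missing = {}, {}, {}, []
    for c in range(K):
        pos = y_true == c
        if pos.sum() == 0 or pos.sum() == len(y_true):
            missing.append(c)
            continue
        f, t, _ = _sk_roc_curve(pos.astype(int), scores[:, c])
        fpr[c], tpr[c] = f, t
        auc[c] = float(np.trapezoid(t, f))
    defined = list(auc.values())
    macro = float(np.mean(defined)) if defined else float("nan")
    return RocCurve(fpr, tpr, auc, macro, missing)


@dataclass
class AblationRow:
    variant: str
    parameters_millions: float
    flops: int
    test_accuracy: float | None = None
    training_time_s: float | None = None


def ablation_report(variants, cfg=None, evaluate_fn=None) -> list:
    """Accounting (and optionally accuracy) rows for the ablation table.

    ``evaluate_fn(model) -> (test_accuracy, training_time_s)`` is only
    called when provided; the accounting columns never require training.
    """
    from .accounting import count_flops, count_parameters
    from .model import build_variant

    if not variants:
        raise ValueError("variant list is empty")
    rows = []
    for name in variants:
        model = build_variant(name, cfg)
        params_m = round(count_parameters(model) / 1e6, 3)
        flops = count_flops(model)
        acc, seconds = (None, None)
        if evaluate_fn is not None:
            acc, seconds = evaluate_fn(model)
        rows.append(AblationRow(name, params_m, flops, acc, seconds))
    return rows


def ablation_to_csv(rows, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["method", "total_parameters_millions", "flops", "test_accuracy_pct", "training_time_s"]
        )
        for r in rows:
            writer.writerow(
                [r.variant, r.parameters_millions, r.flops,
                 "" if r.test_accuracy is None else round(100 * r.test_accuracy, 2),
                 "" if r.training_time_s is None else round(r.training_time_s, 3)]
            )
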