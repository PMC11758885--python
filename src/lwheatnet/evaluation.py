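"""Evaluation: confusion matrices, per-class and support-weighted metrics,
and the three-variant ablation report.

Weighted aggregates use class weights w_i = S_i / S (true-class support over
total).  The weighted F1 is the harmonic combination of the weighted
precision and recall,

    F1_w = 2 * P_w * R_w / (P_w + R_w),

not the more common support-weighted mean of per-class F1 scores.  All 0/0
ratios are defined as 0 (zero-division convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (ModelConfig, build_model, count_parameters,
                         format_param_count, VARIANTS)
from .training import TrainConfig, evaluate_loss_accuracy, fit

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "WeightedMetrics",
    "confusion_matrix",
    "per_class_metrics",
    "accuracy",
    "weighted_metrics",
    "evaluate_model",
    "ablation_report",
    "export_confusion_matrix",
    "render_report",
]


@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predicted classes."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.labels:
            self.labels = [str(i) for i in range(self.matrix.shape[0])]

    @property
    def num_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and ratios per class (arrays of length K)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray


@dataclass
class WeightedMetrics:
    """Support-weighted aggregate metrics, all on the [0, 1] scale."""

    accuracy: float
    precision_w: float
    recall_w: float
    f1_w: float
    weights: np.ndarray


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     labels: list[str] | None = None) -> ConfusionMatrix:
    """Accumulate true/predicted label pairs into a K x K count table."""
    yt = np.asarray(true_labels, dtype=np.int64)
    yp = np.asarray(predicted_labels, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ValueError("true and predicted label sequences differ in length")
    for name, arr in (("true", yt), ("predicted", yp)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels out of range [0, {num_classes})")
    m = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(m, (yt, yp), 1)
    return ConfusionMatrix(m, labels or [])


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest TP/FP/FN/TN with precision = TP/(TP+FP),
    recall = TP/(TP+FN) and F1 = 2PR/(P+R); 0/0 cells are 0."""
    m = cm.matrix
    tp = np.diag(m).astype(np.float64)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    return ClassMetrics(tp=tp, fp=fp, fn=fn, tn=tn,
                        precision=precision, recall=recall, f1=f1)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace / total."""
    total = cm.total
    if total == 0:
        raise ValueError("accuracy of an empty confusion matrix is undefined")
    return float(np.trace(cm.matrix) / total)


def weighted_metrics(cm: ConfusionMatrix) -> WeightedMetrics:
    """Support-weighted precision/recall and their harmonic F1."""
    total = cm.total
    if total == 0:
        raise ValueError("metrics of an empty confusion matrix are undefined")
    pcm = per_class_metrics(cm)
    weights = cm.matrix.sum(axis=1) / total
    precision_w = float((weights * pcm.precision).sum())
    recall_w = float((weights * pcm.recall).sum())
    denom = precision_w + recall_w
    f1_w = 2.0 * precision_w * recall_w / denom if denom > 0 else 0.0
    return WeightedMetrics(accuracy=accuracy(cm), precision_w=precision_w,
                           recall_w=recall_w, f1_w=f1_w, weights=weights)


def evaluate_model(model, x: np.ndarray, y: np.ndarray,
                   labels: list[str] | None = None) -> dict:
    """Loss, confusion matrix and weighted metrics of a model on one split."""
    loss, _ = evaluate_loss_accuracy(model, x, y)
    preds = model.predict(x)
    cm = confusion_matrix(y, preds, model.config.num_classes, labels)
    wm = weighted_metrics(cm)
    return {"loss": loss, "confusion_matrix": cm, "metrics": wm}


def ablation_report(splits, model_cfg: ModelConfig, train_cfg: TrainConfig,
                    variants: tuple[str, ...] = VARIANTS,
                    labels: list[str] | None = None) -> pd.DataFrame:
    """Train every build variant on the same splits and tabulate loss,
    accuracy, weighted metrics (percent) and parameter count per variant.

    ``splits`` carries ``train``/``val``/``test`` attributes, each an
    ``(X, y)`` pair (``val`` may be None).
    """
    rows = []
    for variant in variants:
        cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "variant": variant})
        model = build_model(cfg)
        fit(model, splits.train, train_cfg, val_data=getattr(splits, "val", None))
        result = evaluate_model(model, splits.test[0], splits.test[1], labels)
        wm = result["metrics"]
        rows.append({
            "Model": variant,
            "Loss": round(result["loss"], 4),
            "Accuracy (%)": round(100.0 * wm.accuracy, 2),
            "Precision_w (%)": round(100.0 * wm.precision_w, 2),
            "Recall_w (%)": round(100.0 * wm.recall_w, 2),
            "F1_w (%)": round(100.0 * wm.f1_w, 2),
            "Params": format_param_count(count_parameters(model).total),
        })
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of the ablation table."""
    return report.to_string(index=False)


def export_confusion_matrix(cm: ConfusionMatrix, csv_path, png_path=None) -> None:
    """Write the confusion matrix as CSV and, optionally, a heatmap image."""
    cm.to_frame().to_csv(csv_path)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(cm.matrix, cmap="Blues")
        ax.set_xticks(range(cm.num_classes), cm.labels, rotation=45, ha="right")
        ax.set_yticks(range(cm.num_classes), cm.labels)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(cm.num_classes):
            for j in range(cm.num_classes):
                ax.text(j, i, str(cm.matrix[i, j]), ha="center", va="center",
                        fontsize=8)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
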