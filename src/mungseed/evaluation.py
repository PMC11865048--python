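"""Confusion matrix, per-class metrics and Grad-CAM heatmaps.

Confusion-matrix orientation: rows are the actual class, columns the
predicted class. Per-class precision/recall/F1 are one-vs-rest; the "Avg"
figures are unweighted (macro) means. A class with an undefined metric
(zero denominator) reports 0 and raises a flag instead of being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

__all__ = ["confusion_matrix", "ClassMetrics", "metrics_from_confusion",
           "f1_from_pr", "grad_cam"]


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); algebraically 2TP/(2TP+FP+FN). 0 when P+R=0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with cell (i, j) = #samples of actual class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be 1-D and equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class and macro-averaged accuracy/precision/recall/F1."""

    accuracy: np.ndarray   # per class, (TP+TN)/total
    precision: np.ndarray  # TP/(TP+FP)
    recall: np.ndarray     # TP/(TP+FN)
    f1: np.ndarray         # 2TP/(2TP+FP+FN)
    overall_accuracy: float  # trace/total
    undefined: np.ndarray  # classes where P or R had a zero denominator

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())


def metrics_from_confusion(cm: np.ndarray) -> ClassMetrics:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe(num, den):
        den = np.asarray(den, dtype=np.float64)
        out = np.zeros_like(num, dtype=np.float64)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out, ~ok

    precision, p_undef = safe(tp, tp + fp)
    recall, r_undef = safe(tp, tp + fn)
    f1, _ = safe(2 * tp, 2 * tp + fp + fn)
    accuracy, _ = safe(tp + tn, np.full_like(tp, float(total)))
    overall = float(tp.sum() / total) if total else 0.0
    return ClassMetrics(accuracy=accuracy, precision=precision, recall=recall,
                        f1=f1, overall_accuracy=overall,
                        undefined=p_undef | r_undef)


def grad_cam(model, image: np.ndarray, target_class: int,
             feature_index: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation heatmap at input resolution.

    Channel weights are the spatial means of the target logit's gradient at
    the chosen feature layer; the heatmap is the rectified weighted sum of
    that layer's feature maps, min-max normalised to [0, 1] and upsampled
    bilinearly. A constant map (e.g. all-zero input through a bias-free
    model) degenerates to flat zeros.
    """
    if image.ndim == 3 and image.shape[-1] == 3:
        image = image.transpose(2, 0, 1)
    if image.ndim != 3:
        raise ValueError("expected one RGB image")
    if feature_index is None:
        feature_index = model.n_bottlenecks  # last bottleneck's output
    if not 0 <= feature_index < len(model.features):
        raise ValueError(f"feature_index {feature_index} out of range")

    x = image[None]
    model.set_training(False)
    logits = model.forward(x, keep_features=True)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError("target_class out of range")
    fmap = model._feature_outputs[feature_index][0]
    if fmap.ndim != 3:
        raise ValueError("chosen layer has no spatial feature maps")
    grad_logits = np.zeros_like(logits)
    grad_logits[0, target_class] = 1.0
    grad = model.backward(grad_logits, to_feature=feature_index)[0]

    weights = grad.mean(axis=(1, 2))                      # (C,)
    cam = np.maximum((weights[:, None, None] * fmap).sum(axis=0), 0.0)
    rng_span = cam.max() - cam.min()
    cam = (cam - cam.min()) / rng_span if rng_span > 0 else np.zeros_like(cam)
    return transform.resize(cam, image.shape[1:], order=1,
                            anti_aliasing=False, preserve_range=True)
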