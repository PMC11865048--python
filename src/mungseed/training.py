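"""Cross-entropy loss, the "95-Gradient" step-decay schedule and SGD training.

Hyperparameters mirror the published recipe: 224x224 input, 100 epochs, SGD,
batch 64, initial learning rate 0.01 multiplied by 0.95 every 2 epochs
(stepwise-constant within each window). Momentum 0.9 and zero weight decay
are this package's defaults — the original recipe names only "SGD" — and are
recorded in the run config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.core import Module
from .synthetic import load_image
from PIL import Image

__all__ = [
    "TrainConfig",
    "cross_entropy",
    "softmax",
    "lr_at_epoch",
    "SGD",
    "load_manifest_images",
    "train",
    "evaluate_model",
]

_EPS = 1e-12  # probability clamp for log stability


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    input_size: int = 224
    lr0: float = 0.01
    decay_rate: float = 0.95
    decay_every: int = 2
    momentum: float = 0.9
    weight_decay: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0.0 < self.decay_rate <= 1.0:
            raise ValueError("decay_rate must lie in (0, 1]")
        if self.decay_every < 1:
            raise ValueError("decay_every must be >= 1")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, label: int) -> float:
    """Multiclass cross entropy -sum_c y_c log p_c = -log p_label.

    ``probs`` must be a probability vector; a zero probability at the true
    label is clamped at 1e-12, returning a large finite loss.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1:
        raise ValueError("probs must be a 1-D probability vector")
    if (probs < -1e-9).any() or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("probs must form a probability distribution")
    if not 0 <= label < probs.size:
        raise ValueError("label out of range")
    return float(-np.log(max(probs[label], _EPS)))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean loss over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], _EPS, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step decay: lr(e) = lr0 * rate^floor(e / every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return config.lr0 * config.decay_rate ** (epoch // config.decay_every)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Module, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(model.params())
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= lr * v


def load_manifest_images(manifest: pd.DataFrame, input_size: int,
                         class_names=None):
    """Load, resize and stack manifest images as (N, 3, S, S) in [0, 1].

    Returns ``(images, labels, class_names)`` with integer labels indexing the
    sorted class-name list (pass ``class_names`` to pin an existing order).
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if class_names is None:
        class_names = sorted(manifest["label"].astype(str).unique())
    index = {name: i for i, name in enumerate(class_names)}
    images = np.empty((len(manifest), 3, input_size, input_size))
    labels = np.empty(len(manifest), dtype=np.int64)
    for i, rec in enumerate(manifest.itertuples(index=False)):
        rgb = load_image(rec.path)
        if rgb.shape[:2] != (input_size, input_size):
            im = Image.fromarray((rgb * 255).round().astype(np.uint8))
            rgb = np.asarray(im.resize((input_size, input_size), Image.BILINEAR),
                             dtype=np.float64) / 255.0
        images[i] = rgb.transpose(2, 0, 1)
        labels[i] = index[str(rec.label)]
    return images, labels, list(class_names)


def evaluate_model(model: Module, images: np.ndarray, labels: np.ndarray,
                   batch_size: int = 64):
    """Mean loss, accuracy and predictions on a stacked image array."""
    model.set_training(False)
    losses, preds = [], []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        y = labels[start:start + batch_size]
        logits = model.forward(batch)
        loss, _ = softmax_cross_entropy(logits, y)
        losses.append(loss * len(batch))
        preds.append(logits.argmax(axis=1))
    preds = np.concatenate(preds)
    loss = float(np.sum(losses) / len(images))
    acc = float((preds == labels).mean())
    return loss, acc, preds


def train(model: Module, train_manifest: pd.DataFrame, val_manifest: pd.DataFrame,
          config: TrainConfig = TrainConfig(), class_names=None):
    """Seeded SGD training loop with per-epoch validation.

    Returns ``(history, best_state)``: a frame with columns (epoch, lr,
    train_loss, train_acc, val_loss, val_acc) and the parameter state of the
    epoch with the highest validation accuracy (ties broken by lower
    validation loss).
    """
    if train_manifest.empty or val_manifest.empty:
        raise ValueError("train and validation manifests must be non-empty")
    x_tr, y_tr, class_names = load_manifest_images(
        train_manifest, config.input_size, class_names)
    x_va, y_va, _ = load_manifest_images(val_manifest, config.input_size, class_names)

    rng = np.random.default_rng(config.rng_seed)
    opt = SGD(model, momentum=config.momentum, weight_decay=config.weight_decay)
    history = []
    best = (-1.0, math.inf, None)  # (val_acc, val_loss, state)
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        model.set_training(True)
        order = rng.permutation(len(x_tr))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_tr[idx])
            loss, grad = softmax_cross_entropy(logits, y_tr[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {start // config.batch_size}")
            model.zero_grad()
            model.backward(grad)
            opt.step(lr)
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == y_tr[idx]).sum())
        train_loss = epoch_loss / len(x_tr)
        train_acc = correct / len(x_tr)
        val_loss, val_acc, _ = evaluate_model(model, x_va, y_va, config.batch_size)
        history.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                        "train_acc": train_acc, "val_loss": val_loss,
                        "val_acc": val_acc})
        if (val_acc, -val_loss) > (best[0], -best[1]):
            best = (val_acc, val_loss, model.state_dict())
    return pd.DataFrame(history), best[2]
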