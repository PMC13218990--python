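"""Cross-entropy objective, orientation/stain-preserving augmentation, and the
seeded training loop with best-validation checkpoint selection."""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from .config import TrainConfig
from .model import FreqViT, build_optimizer
from .nn import softmax

__all__ = [
    "cross_entropy",
    "loss_and_grad",
    "augment",
    "rotate90",
    "stratified_split",
    "TrainLog",
    "train",
]

_PROB_FLOOR = 1e-12


def cross_entropy(probs: np.ndarray, label: int) -> float:
    """One-hot cross-entropy ``-log p[label]`` with the probability floored at 1e-12."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1:
        raise ValueError("probs must be a vector of class probabilities")
    if not (0 <= label < probs.shape[0]):
        raise ValueError(f"label {label} out of range [0, {probs.shape[0]})")
    return float(-np.log(max(float(probs[label]), _PROB_FLOOR)))


def loss_and_grad(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits."""
    b = logits.shape[0]
    probs = softmax(logits, axis=-1)
    picked = np.maximum(probs[np.arange(b), labels], _PROB_FLOOR)
    loss = float(-np.log(picked).mean())
    grad = probs.copy()
    grad[np.arange(b), labels] -= 1.0
    return loss, grad / b


def rotate90(image: np.ndarray, k: int) -> np.ndarray:
    """Rotate a channel-first image by ``k`` quarter turns."""
    return np.rot90(image, k=k, axes=(1, 2)).copy()


def _color_jitter(hwc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    brightness = rng.uniform(0.9, 1.1)
    contrast = rng.uniform(0.9, 1.1)
    saturation = rng.uniform(0.9, 1.1)
    hue = rng.uniform(-0.02, 0.02)
    out = hwc * brightness
    mean = out.mean()
    out = mean + (out - mean) * contrast
    luma = out @ np.array([0.299, 0.587, 0.114])
    out = luma[..., None] + (out - luma[..., None]) * saturation
    out = np.clip(out, 0.0, 1.0)
    hsv = rgb2hsv(out)
    hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
    return hsv2rgb(hsv)


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    *,
    flips: bool = True,
    rotations: bool = True,
    jitter: bool = True,
    crop: bool = True,
) -> np.ndarray:
    """Label-preserving augmentation of one RGB image (3, S, S) in [0, 1].

    Applies, in order: horizontal flip (p=0.5), vertical flip (p=0.5), a
    quarter-turn rotation drawn from {0, 90, 180, 270} degrees, mild colour
    jitter (brightness/contrast/saturation in [0.9, 1.1], hue in +-0.02), and a
    random resized crop with area scale in [0.8, 1.0].  Each sub-op can be
    disabled; with all disabled the output equals the input.
    """
    out = np.asarray(image, dtype=np.float64)
    if out.ndim != 3 or out.shape[0] != 3:
        raise ValueError(f"expected (3, S, S) image, got {out.shape}")
    size = out.shape[1]
    if flips:
        if rng.random() < 0.5:
            out = out[:, :, ::-1]
        if rng.random() < 0.5:
            out = out[:, ::-1, :]
    if rotations:
        out = np.rot90(out, k=int(rng.integers(0, 4)), axes=(1, 2))
    out = np.ascontiguousarray(out)
    if jitter or crop:
        hwc = out.transpose(1, 2, 0)
        if jitter:
            hwc = _color_jitter(hwc, rng)
        if crop:
            area = rng.uniform(0.8, 1.0) * size * size
            log_ratio = rng.uniform(np.log(3.0 / 4.0), np.log(4.0 / 3.0))
            ratio = np.exp(log_ratio)
            ch = min(size, max(1, int(round(np.sqrt(area / ratio)))))
            cw = min(size, max(1, int(round(np.sqrt(area * ratio)))))
            top = int(rng.integers(0, size - ch + 1))
            left = int(rng.integers(0, size - cw + 1))
            patch = hwc[top : top + ch, left : left + cw]
            hwc = resize(
                patch, (size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
        out = hwc.transpose(2, 0, 1)
    return np.clip(out, 0.0, 1.0)


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled index split; returns (train_idx, val_idx)."""
    labels = np.asarray(labels)
    train_idx: List[int] = []
    val_idx: List[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


@dataclass
class TrainLog:
    records: List[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrainLog) and self.records == other.records


def _eval_accuracy(model: FreqViT, images: np.ndarray, labels: np.ndarray,
                   batch_size: int = 64) -> float:
    correct = 0
    for start in range(0, images.shape[0], batch_size):
        logits = model.forward(images[start : start + batch_size])
        correct += int((logits.argmax(axis=-1) == labels[start : start + batch_size]).sum())
    return correct / images.shape[0]


def _log(msg: str) -> None:
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    print(f"[{stamp}] {msg}", file=sys.stderr)


def train(
    model: FreqViT,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    verbose: bool = False,
) -> Tuple[FreqViT, TrainLog]:
    """Train in place; returns the model restored to its best-validation weights.

    The split is stratified by label at ``config.val_fraction``; ties in
    validation accuracy are broken toward the earlier epoch.  Everything is
    driven by ``config.seed``, so two runs with identical inputs produce
    identical logs and weights.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if images.shape[0] == 0:
        raise ValueError("empty dataset")
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes in the labels")
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = stratified_split(labels, config.val_fraction, rng)
    if np.unique(labels[train_idx]).size < 2:
        raise ValueError("training split is single-class; provide more data")
    x_tr, y_tr = images[train_idx], labels[train_idx]
    x_va, y_va = images[val_idx], labels[val_idx]

    opt = build_optimizer(model, lr=config.lr, weight_decay=config.weight_decay)
    log = TrainLog()
    best_acc, best_epoch, best_weights = -1.0, -1, model.copy_weights()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        lr = config.lr
        if config.cosine_schedule:
            lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * (epoch - 1) / config.epochs))
        losses, correct = [], 0
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = x_tr[idx]
            if config.augment:
                batch = np.stack(
                    [
                        augment(img, np.random.default_rng(rng.integers(2**63)))
                        for img in batch
                    ]
                )
            logits = model.forward(batch, train=True)
            loss, g = loss_and_grad(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(g)
            opt.step(lr=lr)
            losses.append(loss)
            correct += int((logits.argmax(axis=-1) == y_tr[idx]).sum())
        train_loss = float(np.mean(losses))
        train_acc = correct / order.size
        val_acc = _eval_accuracy(model, x_va, y_va)
        log.append(
            epoch=epoch,
            train_loss=train_loss,
            train_acc=round(train_acc, 6),
            val_acc=round(val_acc, 6),
        )
        if verbose:
            _log(
                f"epoch {epoch}/{config.epochs} loss {train_loss:.4f} "
                f"train_acc {train_acc:.3f} val_acc {val_acc:.3f}"
            )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = model.copy_weights()
    model.load_state_arrays(best_weights)
    return model, log
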