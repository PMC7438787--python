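"""Training recipe for the patch classifier.

The full-scale recipe: batch 64, cross-entropy over the three classes, Adam
with weight decay 1e-5, learning rate 1e-3 for epochs 1-10 then 1e-4 for
epochs 11-20, random horizontal/vertical flips, and per-channel
normalisation with mean (0.485, 0.456, 0.406) and sd (0.229, 0.224, 0.225).
The same normalisation is applied at inference time — the constants are the
usual natural-image ones and are kept for synthetic data too, since only
train/inference consistency matters, not their provenance.

Tests and the default pipeline run a scaled profile (fewer patches and
epochs with the schedule compressed proportionally); the recipe itself is
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PatchSet, kfold_partition
from .nn import Adam, NetworkSpec, ResNet18Classifier, build_classifier

__all__ = [
    "TrainingConfig",
    "lr_for_epoch",
    "normalize_images",
    "recalibrate_batchnorm",
    "train_classifier",
    "evaluate_classifier",
    "run_cross_validation",
    "NORM_MEAN",
    "NORM_SD",
]

NORM_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
NORM_SD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    epochs: int = 20
    #: piecewise-constant schedule: (last_epoch, lr) segments, 1-based epochs
    lr_schedule: tuple[tuple[int, float], ...] = ((10, 1e-3), (20, 1e-4))
    weight_decay: float = 1e-5
    augment_flips: bool = True
    norm_mean: tuple[float, float, float] = tuple(NORM_MEAN)
    norm_sd: tuple[float, float, float] = tuple(NORM_SD)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if any(lr < 0 for _, lr in self.lr_schedule):
            raise ValueError("learning rates must be >= 0")


def lr_for_epoch(config: TrainingConfig, epoch: int) -> float:
    """Learning rate of a 1-based epoch under the piecewise schedule."""
    for last_epoch, lr in config.lr_schedule:
        if epoch <= last_epoch:
            return lr
    return config.lr_schedule[-1][1]


def normalize_images(images: np.ndarray, config: TrainingConfig | None = None) -> np.ndarray:
    """(N, H, W, 3) images in [0, 1] -> normalised (N, 3, H, W) float32."""
    mean = np.asarray(config.norm_mean if config else NORM_MEAN, dtype=np.float32)
    sd = np.asarray(config.norm_sd if config else NORM_SD, dtype=np.float32)
    x = (np.asarray(images, dtype=np.float32) - mean) / sd
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(np.float32)


def _check_patchset(pset: PatchSet, name: str) -> None:
    if len(pset) == 0:
        raise ValueError(f"{name} patch set is empty")
    present = set(np.unique(pset.labels).tolist())
    if not present <= {0, 1, 2}:
        raise ValueError(f"{name} labels outside {{0,1,2}}: {sorted(present)}")
    missing = {0, 1, 2} - present
    if missing:
        warnings.warn(f"{name} set lacks class(es) {sorted(missing)}; loss remains defined")


def train_classifier(
    train_patches: PatchSet,
    val_patches: PatchSet,
    config: TrainingConfig,
    net: ResNet18Classifier | None = None,
    spec: NetworkSpec | None = None,
) -> tuple[ResNet18Classifier, pd.DataFrame]:
    """Train the modified ResNet18 and return (model, history).

    History has one row per epoch: epoch, lr, train_loss (mean over batches)
    and val_accuracy.  The final-epoch model is returned — no early stopping.
    Deterministic under ``config.seed`` (init, shuffling, flip augmentation).
    """
    _check_patchset(train_patches, "train")
    _check_patchset(val_patches, "validation")
    rng = np.random.default_rng(config.seed)
    if net is None:
        net = build_classifier(spec, seed=int(rng.integers(2**31)))
    opt = Adam(net.named_parameters(), weight_decay=config.weight_decay)

    x_train = normalize_images(train_patches.images, config)
    y_train = train_patches.labels
    x_val = normalize_images(val_patches.images, config)
    y_val = val_patches.labels

    history = []
    n = len(y_train)
    for epoch in range(1, config.epochs + 1):
        lr = lr_for_epoch(config, epoch)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if config.augment_flips:
                flip_h = rng.random(len(idx)) < 0.5
                flip_v = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip_h] = xb[flip_h, :, :, ::-1]
                xb[flip_v] = xb[flip_v, :, ::-1, :]
            logits = net.forward(np.ascontiguousarray(xb), train=True)
            loss, dlogits = _softmax_ce(logits, y_train[idx])
            losses.append(loss)
            net.backward(dlogits)
            opt.step()
        if epoch == config.epochs:
            recalibrate_batchnorm(net, x_train, config.batch_size)
        val_acc = _accuracy(net, x_val, y_val, config.batch_size)
        history.append(
            {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
    return net, pd.DataFrame(history)


def recalibrate_batchnorm(net: ResNet18Classifier, x: np.ndarray, batch_size: int = 64) -> None:
    """Replace batch-norm running moments with exact averages over `x`.

    Short training runs take few optimiser steps, so the momentum-based
    running estimates can lag the weights badly at evaluation time.  One
    extra pass in training mode with a cumulative-moving-average momentum
    sets each layer's moments to the mean of its batch statistics.
    """
    from .nn import BatchNorm2d

    bns = [layer for _, layer in net.sublayers() if isinstance(layer, BatchNorm2d)]
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    saved = [bn.momentum for bn in bns]
    try:
        for b, start in enumerate(range(0, len(x), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (b + 1)
            net.forward(x[start : start + batch_size], train=True)
    finally:
        for bn, mom in zip(bns, saved):
            bn.momentum = mom


def _accuracy(net: ResNet18Classifier, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    preds = _predict_labels(net, x, batch_size)
    return float((preds == y).mean())


def _predict_labels(net: ResNet18Classifier, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(x), batch_size):
        logits = net.forward(x[start : start + batch_size], train=False)
        out.append(logits.argmax(axis=1))
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def evaluate_classifier(
    net: ResNet18Classifier, patches: PatchSet, config: TrainingConfig | None = None
) -> tuple[float, np.ndarray]:
    """(accuracy, predicted labels) of the classifier on a patch set."""
    config = config or TrainingConfig()
    x = normalize_images(patches.images, config)
    preds = _predict_labels(net, x, config.batch_size)
    return float((preds == patches.labels).mean()), preds


def run_cross_validation(
    patches: PatchSet, k: int, config: TrainingConfig
) -> dict:
    """k-fold cross-validation: train k models, each validated on its
    held-out fold; returns per-fold accuracies and mean/min/max/sd."""
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = kfold_partition(len(patches), k, seed=config.seed)
    accs = []
    for i, fold in enumerate(folds):
        val = patches.subset(fold)
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        train = patches.subset(train_idx)
        if len(set(np.unique(val.labels)) | set(np.unique(train.labels))) < 3:
            warnings.warn(f"fold {i} is missing a class")
        fold_config = TrainingConfig(
            **{**config.__dict__, "seed": config.seed + 1000 * (i + 1)}
        )
        net, _ = train_classifier(train, val, fold_config)
        acc, _ = evaluate_classifier(net, val, config)
        accs.append(acc)
    accs = np.array(accs)
    return {
        "fold_accuracies": accs,
        "mean": float(accs.mean()),
        "min": float(accs.min()),
        "max": float(accs.max()),
        "sd": float(accs.std(ddof=1)) if k > 1 else 0.0,
    }
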