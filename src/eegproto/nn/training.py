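"""Losses, batch augmentations, the Adam optimizer, and the training loop.

Augmentations (input Gaussian noise inside the model, MixUp here) apply to
training batches only; validation and test data pass through untouched. The
loop checkpoints the weights with the best validation ROC AUC and restores
them before returning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..records import ConfigurationError
from .autodiff import Tensor
from .architectures import Model

_EPS = 1e-7


def focal_loss(y: np.ndarray, p: Tensor, alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Binary focal loss, batch mean: -alpha_t * (1 - p_t)^gamma * log(p_t)."""
    y = np.asarray(y, dtype=np.float64).reshape(p.shape)
    p = p.clip(_EPS, 1.0 - _EPS)
    pt = p * y + (1.0 - p) * (1.0 - y)
    alpha_t = alpha * y + (1.0 - alpha) * (1.0 - y)
    return (-(alpha_t) * (1.0 - pt) ** gamma * pt.log()).mean()


def bce_loss(y: np.ndarray, p: Tensor) -> Tensor:
    """Binary cross-entropy, batch mean (equals focal with gamma=0, alpha=0.5, x2)."""
    y = np.asarray(y, dtype=np.float64).reshape(p.shape)
    p = p.clip(_EPS, 1.0 - _EPS)
    return (-(y * p.log() + (1.0 - y) * (1.0 - p).log())).mean()


def mixup_batch(
    inputs: tuple[np.ndarray, ...], y: np.ndarray, alpha: float, rng: np.random.Generator
) -> tuple[tuple[np.ndarray, ...], np.ndarray]:
    """Convex combination of the batch with a random permutation of itself."""
    if y.shape[0] < 2:
        raise ConfigurationError("mixup requires batch size >= 2")
    lam = float(rng.beta(alpha, alpha)) if alpha > 0 else 1.0
    perm = rng.permutation(y.shape[0])
    mixed_inputs = tuple(lam * a + (1.0 - lam) * a[perm] for a in inputs)
    mixed_y = lam * y + (1.0 - lam) * y[perm]
    return mixed_inputs, mixed_y


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 150
    loss: str = "focal"  # "focal" | "bce"
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    mixup_alpha: float = 0.2  # 0 disables MixUp
    schedule: str | None = "plateau"  # "cosine_restarts" | "plateau" | None
    cosine_first_period: int = 10
    cosine_period_mult: int = 2
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-5
    seed: int = 0


def _cosine_restarts_lr(epoch: int, base_lr: float, first_period: int, mult: int, min_lr: float) -> float:
    period, start = first_period, 0
    while epoch >= start + period:
        start += period
        period *= mult
    frac = (epoch - start) / period
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * frac))


def _window_auc(y: np.ndarray, scores: np.ndarray) -> float:
    # Mann-Whitney AUC with ties counted one half; 0.5 for single-class input.
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return 0.5
    order = np.argsort(np.concatenate([neg, pos]), kind="mergesort")
    ranks = np.empty(len(order))
    combined = np.concatenate([neg, pos])[order]
    # average ranks for ties
    sorted_vals = combined
    ranks_sorted = np.arange(1, len(order) + 1, dtype=np.float64)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks_sorted[i : j + 1] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    ranks[order] = ranks_sorted
    r_pos = ranks[len(neg):].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def train_model(
    model: Model,
    train_inputs: tuple[np.ndarray, ...],
    y_train: np.ndarray,
    val_inputs: tuple[np.ndarray, ...],
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> dict:
    """Train and return history; model is left holding the best-val-AUC weights."""
    if y_train.size == 0:
        raise ConfigurationError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    opt = Adam(model.params(), lr=config.lr)
    n = y_train.shape[0]
    history = {"loss": [], "acc": [], "val_auc": [], "val_acc": [], "lr": []}
    best_auc, best_weights = -np.inf, model.get_weights()
    plateau_wait = 0
    current_lr = config.lr

    for epoch in range(config.epochs):
        if config.schedule == "cosine_restarts":
            current_lr = _cosine_restarts_lr(
                epoch, config.lr, config.cosine_first_period,
                config.cosine_period_mult, config.min_lr,
            )
        opt.lr = current_lr

        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch_inputs = tuple(a[idx] for a in train_inputs)
            yb = y_train[idx].astype(np.float64)
            if config.mixup_alpha > 0 and len(idx) >= 2:
                batch_inputs, yb = mixup_batch(batch_inputs, yb, config.mixup_alpha, rng)
            p = model.forward(batch_inputs, training=True, rng=rng)
            if config.loss == "focal":
                loss = focal_loss(yb, p, config.focal_alpha, config.focal_gamma)
            else:
                loss = bce_loss(yb, p)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int(((p.data.ravel() >= 0.5) == (y_train[idx] == 1)).sum())

        val_scores = model.predict_proba(val_inputs)
        val_auc = _window_auc(y_val, val_scores)
        history["loss"].append(epoch_loss / n)
        history["acc"].append(epoch_correct / n)
        history["val_auc"].append(val_auc)
        history["val_acc"].append(float(((val_scores >= 0.5) == (y_val == 1)).mean()))
        history["lr"].append(current_lr)

        if val_auc > best_auc:
            best_auc = val_auc
            best_weights = model.get_weights()
            plateau_wait = 0
        elif config.schedule == "plateau":
            plateau_wait += 1
            if plateau_wait >= config.plateau_patience:
                current_lr = max(current_lr * config.plateau_factor, config.min_lr)
                plateau_wait = 0

    model.set_weights(best_weights)
    history["best_val_auc"] = best_auc
    return history
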