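"""Optimizers, learning-rate scheduling, and loss functions."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Adam:
    """Adaptive-moment optimizer.  Frozen parameters are never touched."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.frozen:
                continue
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored value (lower is better)."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 5,
                 min_lr: float = 1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float):
        if value < self.best - 1e-12:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.min_lr, self.opt.lr * self.factor)
                self.bad_epochs = 0


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: float | None = None):
    """Mean binary cross-entropy on raw logits.  Returns (loss, dlogits)."""
    z = logits.ravel()
    y = targets.ravel().astype(float)
    p = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-12
    w = np.where(y == 1.0, pos_weight if pos_weight is not None else 1.0, 1.0)
    loss = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    dz = w * (p - y) / z.size
    return loss, dz.reshape(logits.shape)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error.  Returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size
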