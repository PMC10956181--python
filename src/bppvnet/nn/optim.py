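"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


class Adam:
    """Adaptive-moment optimiser (Kingma & Ba defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


def sine_decay_lr(initial_lr: float, epoch: int, total_epochs: int) -> float:
    """Half-cosine decay from `initial_lr` at epoch 0 towards 0 at the end."""
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    return initial_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))
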