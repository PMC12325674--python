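"""AdamW optimizer with decoupled weight decay and a cosine learning-rate
schedule decaying to zero by the final epoch."""

from __future__ import annotations

import math

import numpy as np

from .engine import Tensor

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            # decoupled weight decay
            p.data -= self.lr * (update + self.weight_decay * p.data)


def cosine_lr(lr0: float, epoch: int, max_epochs: int) -> float:
    """Cosine annealing from ``lr0`` at epoch 0, reaching zero one step past
    the final epoch (so the last epoch still trains at a small rate)."""
    if max_epochs <= 1:
        return lr0
    frac = min(epoch, max_epochs) / max_epochs
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))
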