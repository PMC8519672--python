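"""Optimizers. RMSProp is the update rule used for both WGAN players."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["RMSProp"]


class RMSProp:
    """RMSProp: v <- a·v + (1-a)·g²;  w <- w − lr·g/(√v + eps)."""

    def __init__(self, params: list[Tensor], lr: float, alpha: float = 0.9,
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._cache = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._cache):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(v) + self.eps)
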