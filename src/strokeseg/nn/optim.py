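"""Optimisers. Only Adam is provided; it is the one the training recipe uses."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments (eps inside the sqrt
    denominator, Keras-style default 1e-7)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params: list[Parameter] = [p for p in params if p.trainable]
        if not self.params:
            raise ValueError("optimizer received no trainable parameters")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= (self.lr * (m / c1)
                       / (np.sqrt(v / c2) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
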