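"""Optimizers (Adam with decoupled-from-loss L2 weight decay, as in the
classic formulation where decay is added to the gradient)."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor


class Adam:
    def __init__(self, params, lr: float = 1e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            step = m / (bc1 * (np.sqrt(v / bc2) + self.eps))
            step *= self.lr
            p.data -= step.astype(DTYPE, copy=False)
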