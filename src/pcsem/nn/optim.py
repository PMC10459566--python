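"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGDM:
    """v <- mu*v - lr*g;  p <- p + v.  Learning rate is set per step."""

    def __init__(self, params: list[Parameter], momentum: float = 0.9):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self.velocity):
            v *= mu
            v -= lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
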