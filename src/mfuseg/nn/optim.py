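"""Optimizers. Only Adagrad is provided — it is the training procedure's
stated optimizer — with the conventional accumulator update
G += g^2;  w -= lr * g / (sqrt(G) + eps).
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adagrad:
    def __init__(self, params, lr: float = 1e-3, eps: float = 1e-10,
                 initial_accumulator: float = 0.0):
        self.params: list[Parameter] = list(params)
        if not self.params:
            raise ValueError("no parameters to optimize")
        self.lr = lr
        self.eps = eps
        self.state = [np.full_like(p.data, initial_accumulator) for p in self.params]

    def step(self) -> None:
        for p, acc in zip(self.params, self.state):
            if p.grad is None:
                continue
            acc += p.grad * p.grad
            p.data -= self.lr * p.grad / (np.sqrt(acc) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
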