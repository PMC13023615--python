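"""Adadelta optimizer (accumulated-gradient / accumulated-update scheme)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adadelta"]


class Adadelta:
    def __init__(self, params, learning_rate: float = 0.05, rho: float = 0.95,
                 eps: float = 1e-6):
        self.params = list(params)
        self.lr = float(learning_rate)
        self.rho = float(rho)
        self.eps = float(eps)
        self._acc_grad = [np.zeros_like(p.data) for p in self.params]
        self._acc_update = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        rho, eps = self.rho, self.eps
        for p, eg, ed in zip(self.params, self._acc_grad, self._acc_update):
            if p.grad is None:
                continue
            g = p.grad
            eg *= rho
            eg += (1.0 - rho) * g * g
            update = -np.sqrt(ed + eps) / np.sqrt(eg + eps) * g
            ed *= rho
            ed += (1.0 - rho) * update * update
            p.data += self.lr * update
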