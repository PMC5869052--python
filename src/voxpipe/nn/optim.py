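"""Gradient-descent optimizers (Adam, plain SGD) over Variable lists."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Variable


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    Defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8) follow common practice;
    the optimizer owns its parameter list, so stepping it never touches
    parameters of other modules.
    """

    def __init__(self, variables, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.variables: list[Variable] = list(variables)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(v.data) for v in self.variables]
        self._v = [np.zeros_like(v.data) for v in self.variables]

    def add_variables(self, variables) -> None:
        """Track parameters created after construction (lazy building)."""
        known = {id(v) for v in self.variables}
        for v in variables:
            if id(v) not in known:
                self.variables.append(v)
                self._m.append(np.zeros_like(v.data))
                self._v.append(np.zeros_like(v.data))

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, var in enumerate(self.variables):
            if var.grad is None:
                continue
            g = var.grad.astype(np.float64)
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
            m_hat = self._m[i] / b1t
            v_hat = self._v[i] / b2t
            var.data = (var.data.astype(np.float64)
                        - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(ad.DTYPE)

    def zero_grad(self) -> None:
        for v in self.variables:
            v.zero_grad()


class SGD:
    def __init__(self, variables, lr: float = 0.1):
        self.variables = list(variables)
        self.lr = float(lr)

    def step(self) -> None:
        for v in self.variables:
            if v.grad is not None:
                v.data = (v.data - self.lr * v.grad).astype(ad.DTYPE)

    def zero_grad(self) -> None:
        for v in self.variables:
            v.zero_grad()
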