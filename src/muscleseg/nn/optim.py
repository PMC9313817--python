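"""Adam optimizer over a named parameter dict."""
from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: dict[str, Param],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2, t = self.b1, self.b2, self._t
        for k, p in self.params.items():
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**t)
            vhat = self._v[k] / (1 - b2**t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0
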