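"""Minimal Adam optimizer over a dict of named parameter arrays.

Parameters are updated in place.  ``step`` takes gradients of the loss
(descent); to ascend an objective pass the negated gradients.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: dict, lr: float | dict = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def _rate(self, name: str) -> float:
        if isinstance(self.lr, dict):
            return self.lr[name]
        return self.lr

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.params:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self._rate(k) * mhat / (np.sqrt(vhat) + self.eps)
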