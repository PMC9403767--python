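"""Adaptive-moment (Adam) optimizer for the NumPy runtime."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with per-step learning rate (for cyclical schedules).

    Defaults match the common framework values (beta1 0.9, beta2 0.999,
    eps 1e-7).  Frozen and non-trainable parameters are skipped; their moment
    buffers are untouched, so freezing is fully reversible.
    """

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(p): np.zeros_like(p.value) for p in params}
        self.v = {id(p): np.zeros_like(p.value) for p in params}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p in self.params:
            if not p.trainable or p.frozen:
                continue
            m = self.m[id(p)]
            v = self.v[id(p)]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
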