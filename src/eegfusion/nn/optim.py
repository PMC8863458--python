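"""Adam optimizer for the layer zoo's ``Param`` objects."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Param


class Adam:
    """Adam with bias-corrected first/second moments.

    Moment decays and epsilon follow the conventional defaults
    (beta1 = 0.9, beta2 = 0.999, eps = 1e-7); the learning rate is supplied
    per step so a schedule can drive it.
    """

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)
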