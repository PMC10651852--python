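"""Nadam optimizer (Adam with Nesterov momentum, Dozat 2016).

Update rule matching the common deep-learning framework implementation:

    m_t = β1·m + (1−β1)·g            v_t = β2·v + (1−β2)·g²
    m̂  = β1·m_t/(1−β1^{t+1}) + (1−β1)·g/(1−β1^t)
    v̂  = v_t/(1−β2^t)
    θ  ← θ − lr·m̂ / (√v̂ + ε)

Parameters are updated in place so that layers sharing array references stay
consistent.
"""

from __future__ import annotations

import numpy as np


class Nadam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc1_next = 1.0 - b1 ** (self.t + 1)
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = (b1 * m) / bc1_next + ((1.0 - b1) * g) / bc1
            v_hat = v / bc2
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
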