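"""Adaptive moment estimation (Adam) for the NumPy network."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for layer, name, p, _ in net.parameters():
            key = (id(layer), name)
            self._m[key] = np.zeros_like(p)
            self._v[key] = np.zeros_like(p)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, name, p, g in self.net.parameters():
            key = (id(layer), name)
            m, v = self._m[key], self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
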