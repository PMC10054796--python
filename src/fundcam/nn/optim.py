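"""Adam optimizer over a Network's parameter handles."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, network, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.network = network
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(layer.params[k]) for layer, k in network.parameters()]
        self._v = [np.zeros_like(layer.params[k]) for layer, k in network.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, key) in enumerate(self.network.parameters()):
            g = layer.grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[key]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1 ** self.t)
            v_hat = self._v[i] / (1 - self.b2 ** self.t)
            layer.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
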