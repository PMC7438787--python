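"""Adam optimiser with L2 weight decay added to the gradient."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        named_params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        # list of (name, layer, param_key)
        self.entries = list(named_params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(layer.params[k]) for n, layer, k in self.entries}
        self.v = {n: np.zeros_like(layer.params[k]) for n, layer, k in self.entries}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, key in self.entries:
            g = layer.grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[key]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, layer, key in self.entries:
            layer.grads[key] = np.zeros_like(layer.params[key])
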