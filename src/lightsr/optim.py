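"""AdamW optimizer and cosine-annealing schedule (pure NumPy)."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies each parameter by ``(1 - lr * weight_decay)``
    before the Adam update, matching the decoupled formulation (applied to
    every parameter, batch-norm affines included).
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            p.data *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cosine_lr(epoch: int, config) -> float:
    """Cosine-annealed learning rate at integer epoch ``0 <= epoch <= T_max``.

    ``lr = eta_min + (lr0 - eta_min) * (1 + cos(pi * epoch / T_max)) / 2``.
    """
    t_max = config.t_max
    if epoch < 0 or epoch > t_max:
        raise ValueError(f"epoch {epoch} outside [0, {t_max}]")
    return config.eta_min + 0.5 * (config.lr0 - config.eta_min) \
        * (1.0 + math.cos(math.pi * epoch / t_max))
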