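"""SGD with momentum, weight decay and a cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class SGD:
    """Momentum SGD with decoupled-from-nothing (classic L2) weight decay.

    ``v <- momentum * v + grad + wd * w``;  ``w <- w - lr * v``.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.1,
        momentum: float = 0.9,
        weight_decay: float = 0.001,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from ``base_lr`` at epoch 0 to 0 at ``total_epochs``."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))
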