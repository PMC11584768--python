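"""Adam optimizer and the cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_annealing(epoch: int, total_epochs: int, lr: float, lr_min: float) -> float:
    """Learning rate at ``epoch`` decaying from ``lr`` (epoch 0) to ``lr_min``
    (final epoch) along a half cosine."""
    if total_epochs <= 1:
        return lr
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr - lr_min) * (1.0 + np.cos(np.pi * t))
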