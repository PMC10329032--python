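"""Adam optimizer with L2-coupled weight decay and a settable learning rate."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter


class Adam:
    """Adam (Kingma & Ba) over a list of parameters.

    ``weight_decay`` is added to the raw gradient (classic L2 coupling),
    matching the convention the reported hyperparameters were stated for.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self._t += 1
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def annealed_lr(base_lr: float, epoch: int, n_epochs: int,
                anneal_after: int, schedule: str = "linear") -> float:
    """Learning rate for ``epoch`` (0-based): constant through
    ``anneal_after`` epochs, then decayed toward zero over the remainder.
    """
    if epoch < anneal_after or n_epochs <= anneal_after:
        return base_lr
    frac = (epoch - anneal_after + 1) / (n_epochs - anneal_after)
    if schedule == "cosine":
        return base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))
    # linear decay; keep a floor of one decay step so the last epoch still moves
    return base_lr * max(1.0 - frac, 1.0 / (2 * (n_epochs - anneal_after)))
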