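"""Optimisation utilities: AdamW, global-norm gradient clipping, LR decay."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "clip_grad_norm", "ExponentialLR"]


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies parameters by (1 - lr*wd) each step, independent
    of the gradient-based update.  Parameters whose ``frozen`` flag is set are
    skipped entirely (no moment updates, no decay).
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.frozen or p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None and not p.frozen]
    for g in grads:
        total += float(np.sum(np.square(g, dtype=np.float64)))
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm


class ExponentialLR:
    """Multiply the optimizer learning rate by ``gamma`` once per epoch."""

    def __init__(self, optimizer: AdamW, gamma: float):
        self.optimizer = optimizer
        self.gamma = float(gamma)

    def step(self):
        self.optimizer.lr *= self.gamma

    @property
    def lr(self) -> float:
        return self.optimizer.lr
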