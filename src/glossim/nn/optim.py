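"""Adam optimizer with global-norm gradient clipping and multiplicative
learning-rate decay."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "clip_global_norm"]


def clip_global_norm(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = np.float32(max_norm / norm)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam over a single flattened parameter buffer (gather/scatter per
    step keeps the moment updates fully vectorized)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.sizes = [p.data.size for p in self.params]
        self.offsets = np.cumsum([0] + self.sizes)
        n = int(self.offsets[-1])
        self.m = np.zeros(n, dtype=np.float32)
        self.v = np.zeros(n, dtype=np.float32)
        self._g = np.zeros(n, dtype=np.float32)

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        g = self._g
        for p, lo, hi in zip(self.params, self.offsets[:-1], self.offsets[1:]):
            if p.grad is not None:
                g[lo:hi] = p.grad.ravel()
            else:
                g[lo:hi] = 0.0
        self.m *= self.b1
        self.m += (1 - self.b1) * g
        self.v *= self.b2
        self.v += (1 - self.b2) * np.square(g)
        denom = np.sqrt(self.v)
        denom *= np.float32(1.0 / np.sqrt(b2t))
        denom += self.eps
        update = (np.float32(self.lr / b1t) * self.m) / denom
        for p, lo, hi in zip(self.params, self.offsets[:-1], self.offsets[1:]):
            p.data -= update[lo:hi].reshape(p.data.shape)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def decay_lr(self, factor: float):
        self.lr *= factor
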