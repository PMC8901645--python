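"""RMSprop with optional per-group learning rates.

Only tensors that received a gradient in the current step are updated, so a
disabled objective's head stays bit-identical to its initialisation.
"""

from __future__ import annotations

import numpy as np


class RMSprop:
    def __init__(self, tensors: dict, lr: float, decay: float = 0.9, eps: float = 1e-8):
        self.tensors = dict(tensors)
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self.cache = {k: np.zeros_like(t.data) for k, t in self.tensors.items()}

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def step(self) -> None:
        for k, t in self.tensors.items():
            g = t.grad
            if g is None:
                continue
            v = self.cache[k]
            v *= self.decay
            v += (1.0 - self.decay) * g * g
            t.data -= (self.lr * g / (np.sqrt(v) + self.eps)).astype(t.data.dtype)
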