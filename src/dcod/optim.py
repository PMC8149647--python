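"""AdamW: adaptive moments with decoupled weight decay.

The decay is applied as a multiplicative shrinkage ``w <- w - lr*wd*w``
separate from the loss-gradient update, so a step taken at exactly zero loss
gradient shrinks every parameter by the factor ``(1 - lr*wd)``.  This
decoupling (rather than folding an L2 term into the gradient) is what makes
weight decay behave as a true regularizer under adaptive step sizes.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    """Minimal AdamW over a list of NumPy parameter arrays (updated in place)."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        learning_rate: float = 0.01,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if weight_decay < 0:
            raise ValueError("weight decay must be nonnegative")
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: List[np.ndarray] = [np.zeros_like(p) for p in params]
        self._v: List[np.ndarray] = [np.zeros_like(p) for p in params]

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        if len(params) != len(self._m) or len(grads) != len(params):
            raise ValueError("params/grads do not match the optimizer state")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        lr = self.learning_rate
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g**2
            if self.weight_decay:
                p *= 1.0 - lr * self.weight_decay
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
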