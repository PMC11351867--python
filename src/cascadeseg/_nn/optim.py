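"""Adam/AdamW optimisers and the polynomial learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "AdamW", "poly_decay"]


def poly_decay(base_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """lr * (1 - step/total)^power; reaches 0 at the final step."""
    frac = min(max(step / max(total_steps, 1), 0.0), 1.0)
    return base_lr * (1.0 - frac) ** power


class Adam:
    """Adam with optional per-parameter-group learning rates.

    ``groups`` is a list of (params, base_lr). Decoupled weight decay is the
    AdamW variant below.
    """

    def __init__(self, groups: list[tuple[list[Tensor], float]],
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.groups = [(list(ps), float(lr)) for ps, lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for ps, _ in self.groups for p in ps}
        self._v = {id(p): np.zeros_like(p.data) for ps, _ in self.groups for p in ps}

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for params, base_lr in self.groups:
            lr = base_lr * lr_scale
            for p in params:
                if p.grad is None:
                    continue
                g = p.grad
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if self.weight_decay:
                    p.data -= lr * self.weight_decay * p.data
                p.data -= lr * update


class AdamW(Adam):
    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        super().__init__(groups, betas=betas, eps=eps, weight_decay=weight_decay)
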