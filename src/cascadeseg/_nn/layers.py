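"""Trainable modules built on the autodiff tensors.

Includes the two attention units the coarse network relies on:
channel recalibration (squeeze-and-excitation) and an embedded-Gaussian
non-local block for long-range spatial context on skip connections.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Linear", "SEBlock", "NonLocalBlock", "ConvBlock"]


class Module:
    """Base class: parameter discovery, freezing, state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.astype(np.float32, copy=True)

    def copy_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.w = _he(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.b = Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        self.w = _he(rng, (in_f, out_f), in_f)
        self.b = Tensor(np.zeros(out_f, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)


class SEBlock(Module):
    """Squeeze-and-excitation: global pooling, two FC layers, sigmoid gate."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8):
        hidden = max(channels // reduction, 2)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        s = ad.global_avg_pool(x)                    # (N, C)
        s = ad.relu(self.fc1(s))
        s = ad.sigmoid(self.fc2(s))                  # channel gates in (0,1)
        n, c = s.data.shape
        gates = ad.reshape(s, (n, c, 1, 1))
        return ad.mul(x, gates)


class NonLocalBlock(Module):
    """Embedded-Gaussian self-attention with a residual connection.

    theta/phi/g are 1x1 convs to channels//2; attention is softmax over
    positions; the output projection is zero-initialised so the block starts
    as identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        inner = max(channels // 2, 1)
        self.inner = inner
        self.theta = Conv2d(channels, inner, 1, rng)
        self.phi = Conv2d(channels, inner, 1, rng)
        self.g = Conv2d(channels, inner, 1, rng)
        self.out = Conv2d(inner, channels, 1, rng)
        self.out.w.data[:] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        hw = h * w
        th = ad.reshape(self.theta(x), (n, self.inner, hw))
        ph = ad.reshape(self.phi(x), (n, self.inner, hw))
        gg = ad.reshape(self.g(x), (n, self.inner, hw))
        attn = ad.bmm(ad.transpose_last2(th), ph)         # (N, HW, HW)
        attn = ad.softmax(ad.mul(attn, 1.0 / np.sqrt(self.inner)), axis=-1)
        y = ad.bmm(gg, ad.transpose_last2(attn))           # (N, inner, HW)
        y = ad.reshape(y, (n, self.inner, h, w))
        return ad.add(x, self.out(y))


class ConvBlock(Module):
    """Two conv(3x3) + instance-norm + ReLU stages, optional SE unit."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 use_se: bool = True, se_reduction: int = 8):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.se = SEBlock(out_ch, rng, se_reduction) if use_se else None

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.relu(ad.instance_norm(self.c1(x)))
        x = ad.relu(ad.instance_norm(self.c2(x)))
        if self.se is not None:
            x = self.se(x)
        return x
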