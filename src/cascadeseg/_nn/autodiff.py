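"""Minimal reverse-mode autodiff on numpy arrays.

Just enough machinery to train small convolutional encoder-decoders on a
CPU: tensors carry a gradient and a closure; ``backward`` runs a
topological sweep. All arithmetic is float32. Shapes follow the (N, C, H, W)
convention used throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "bmm", "relu", "sigmoid", "log", "concat",
    "softmax", "mean_all", "sum_all", "reshape", "transpose_last2",
    "conv2d", "maxpool2x", "upsample2x", "global_avg_pool", "instance_norm",
    "pad_to",
]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn, requires: bool) -> Tensor:
    out = Tensor(data, requires_grad=requires)
    if requires:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward_fn
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over broadcast axes so it matches ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bwd, req)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bwd, req)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bwd, a.requires_grad)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), bwd, a.requires_grad)


def log(a) -> Tensor:
    a = _wrap(a)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bwd, a.requires_grad)


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    """2-D matrix product."""
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bwd, req)


def bmm(a, b) -> Tensor:
    """Batched matrix product on (N, ., .) stacks."""
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

    return _make(a.data @ b.data, (a, b), bwd, req)


def transpose_last2(a) -> Tensor:
    a = _wrap(a)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.swapaxes(g, -1, -2))

    return _make(np.swapaxes(a.data, -1, -2), (a,), bwd, a.requires_grad)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd, a.requires_grad)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bwd, req)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

    return _make(s, (a,), bwd, a.requires_grad)


# -- reductions ------------------------------------------------------------

def mean_all(a) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.full(a.data.shape, float(g) / n, dtype=_DTYPE))

    return _make(a.data.mean(), (a,), bwd, a.requires_grad)


def sum_all(a) -> Tensor:
    a = _wrap(a)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.full(a.data.shape, float(g), dtype=_DTYPE))

    return _make(a.data.sum(), (a,), bwd, a.requires_grad)


def global_avg_pool(a) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    a = _wrap(a)
    n_, c_, h, w = a.data.shape

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(
                g[:, :, None, None] / (h * w), a.data.shape).astype(_DTYPE))

    return _make(a.data.mean(axis=(2, 3)), (a,), bwd, a.requires_grad)


# -- spatial ops -----------------------------------------------------------

def conv2d(x, w, b=None) -> Tensor:
    """Same-padded stride-1 convolution.

    x: (N, C, H, W); w: (O, C, k, k) with k odd; b: (O,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    n, c, h, wd = x.data.shape
    o, c2, k, k2 = w.data.shape
    if c != c2 or k != k2 or k % 2 != 1:
        raise ValueError(f"incompatible conv shapes {x.data.shape} / {w.data.shape}")
    p = k // 2
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = x.data
    # im2col: (N, C*k*k, H*W)
    cols = np.empty((n, c * k * k, h * wd), dtype=_DTYPE)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, idx * c:(idx + 1) * c, :] = \
                xp[:, :, di:di + h, dj:dj + wd].reshape(n, c, h * wd)
            idx += 1
    # weight matrix laid out to match the (dy, dx, channel) column order
    wm = np.ascontiguousarray(
        w.data.transpose(2, 3, 1, 0).reshape(k * k * c, o))
    out = np.matmul(cols.transpose(0, 2, 1), wm)          # (N, L, O) via BLAS
    out = out.transpose(0, 2, 1).reshape(n, o, h, wd)
    if b is not None:
        out = out + b.data[None, :, None, None]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def bwd(g):
        gm = g.reshape(n, o, h * wd)
        if w.requires_grad:
            gw = np.matmul(cols, gm.transpose(0, 2, 1)).sum(axis=0)  # (C9, O)
            w._accumulate(gw.reshape(k, k, c, o).transpose(3, 2, 0, 1))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wm, gm)                      # (N, C9, L)
            gxp = np.zeros_like(xp)
            idx2 = 0
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di:di + h, dj:dj + wd] += \
                        gcols[:, idx2 * c:(idx2 + 1) * c, :].reshape(n, c, h, wd)
                    idx2 += 1
            x._accumulate(gxp[:, :, p:p + h, p:p + wd] if p else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bwd, req)


def maxpool2x(x) -> Tensor:
    """2x2 max pooling, stride 2; even spatial dims required."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x needs even spatial dims")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = (r == out[:, :, :, None, :, None])
    # break ties deterministically: keep first max only
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def bwd(g):
        if x.requires_grad:
            gx = mask * g[:, :, :, None, :, None]
            x._accumulate(gx.reshape(n, c, h, w))

    return _make(out, (x,), bwd, x.requires_grad)


def upsample2x(x) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        if x.requires_grad:
            gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(gr)

    return _make(out, (x,), bwd, x.requires_grad)


def instance_norm(x, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardisation over the spatial axes."""
    x = _wrap(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv

    def bwd(g):
        if x.requires_grad:
            gm = g.mean(axis=(2, 3), keepdims=True)
            gym = (g * y).mean(axis=(2, 3), keepdims=True)
            x._accumulate(inv * (g - gm - y * gym))

    return _make(y, (x,), bwd, x.requires_grad)


def pad_to(x, h: int, w: int) -> Tensor:
    """Zero-pad spatial dims up to (h, w); used for odd-size skip joins."""
    x = _wrap(x)
    n, c, h0, w0 = x.data.shape
    if (h0, w0) == (h, w):
        return x
    out = np.zeros((n, c, h, w), dtype=_DTYPE)
    out[:, :, :h0, :w0] = x.data

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, :, :h0, :w0])

    return _make(out, (x,), bwd, x.requires_grad)
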