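"""A compact reverse-mode autodiff engine over numpy arrays.

Only the operations the two networks need are implemented: 3D convolution
(via 27 shifted einsum contractions), 2x max-pooling, nearest-neighbour
upsampling, batch normalization, ReLU, dense layers, channel concatenation,
dropout and the task losses. Everything is float64 so analytic gradients can
be verified against central differences to ~1e-7.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add_bias",
    "matmul",
    "relu",
    "reshape",
    "concat_channels",
    "conv3d",
    "maxpool2",
    "upsample2",
    "dropout",
    "batchnorm",
]


class Tensor:
    """Array node on the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad and t._backward is None:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    out._backward = backward
    # propagate gradient need through the tape
    out.requires_grad = any(p.requires_grad or p._backward is not None for p in parents)
    return out


def add_bias(x: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    """Add a per-channel bias along ``axis``."""
    shape = [1] * x.data.ndim
    shape[axis] = b.data.size
    out_data = x.data + b.data.reshape(shape)

    def backward(g):
        _accum(x, g)
        axes = tuple(i for i in range(g.ndim) if i != axis)
        _accum(b, g.sum(axis=axes))

    return _node(out_data, (x, b), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out_data = x.data @ w.data

    def backward(g):
        _accum(x, g @ w.data.T)
        _accum(w, x.data.T @ g)

    return _node(out_data, (x, w), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return _node(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        _accum(x, g.reshape(old))

    return _node(out_data, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along axis 1 (channels)."""
    na = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accum(a, g[:, :na])
        _accum(b, g[:, na:])

    return _node(out_data, (a, b), backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding 3D convolution; ``x`` (N,C,D,H,W), ``w`` (O,C,k,k,k)."""
    k = w.data.shape[2]
    pad = k // 2
    n, c, d, h, wd = x.data.shape
    o = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    out_data = np.zeros((n, o, d, h, wd))
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dz : dz + d, dy : dy + h, dx : dx + wd]
                out_data += np.einsum(
                    "oc,ncdhw->nodhw", w.data[:, :, dz, dy, dx], xs, optimize=True
                )
    if b is not None:
        out_data += b.data.reshape(1, o, 1, 1, 1)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    wk = w.data[:, :, dz, dy, dx]
                    xs = xp[:, :, dz : dz + d, dy : dy + h, dx : dx + wd]
                    dxp[:, :, dz : dz + d, dy : dy + h, dx : dx + wd] += np.einsum(
                        "oc,nodhw->ncdhw", wk, g, optimize=True
                    )
                    dw[:, :, dz, dy, dx] = np.einsum("nodhw,ncdhw->oc", g, xs, optimize=True)
        if pad:
            _accum(x, dxp[:, :, pad:-pad, pad:-pad, pad:-pad])
        else:
            _accum(x, dxp)
        _accum(w, dw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial dims must be even.
    Gradient of a tie is split evenly between the tied entries."""
    n, c, d, h, w = x.data.shape
    assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "maxpool2 needs even spatial dims"
    xr = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out_data = xr.max(axis=(3, 5, 7))

    def backward(g):
        oe = out_data[:, :, :, None, :, None, :, None]
        mask = (xr == oe).astype(np.float64)
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        ge = g.reshape(n, c, d // 2, 1, h // 2, 1, w // 2, 1)
        _accum(x, (mask / counts * ge).reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial dims."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(g):
        n, c, d, h, w = x.data.shape
        gr = g.reshape(n, c, d, 2, h, 2, w, 2)
        _accum(x, gr.sum(axis=(3, 5, 7)))

    return _node(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out_data = x.data * keep

    def backward(g):
        _accum(x, g * keep)

    return _node(out_data, (x,), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    momentum: float,
    eps: float,
    training: bool,
) -> Tensor:
    """Per-channel batch normalization over (N, spatial) for (N,C,...) input.
    Updates ``running_mean``/``running_var`` in place during training."""
    axes = (0,) + tuple(range(2, x.data.ndim))
    cshape = [1] * x.data.ndim
    cshape[1] = x.data.shape[1]

    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var

    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * inv.reshape(cshape)
    out_data = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        gi = gamma.data.reshape(cshape) * inv.reshape(cshape)
        if training:
            mean_g = g.mean(axis=axes).reshape(cshape)
            mean_gx = (g * xhat).mean(axis=axes).reshape(cshape)
            _accum(x, gi * (g - mean_g - xhat * mean_gx))
        else:
            _accum(x, gi * g)

    return _node(out_data, (x, gamma, beta), backward)
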