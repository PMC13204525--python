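"""A small reverse-mode autograd over numpy arrays.

Only what the compact 3D models need: broadcast-aware arithmetic, matmul,
shape ops, activations, softmax, 3D convolution (im2col) and average
pooling. Gradients are accumulated in float32; every op's backward pass is
covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float32).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators --------------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_const(self, -1.0)

    def __sub__(self, other):
        return add(self, mul_const(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_const(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.shape)

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.shape)

    out._backward = backward
    return out


def mul_const(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * c

    out._backward = backward
    return out


def pow_const(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data**p, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * p * a.data ** (p - 1)

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g.reshape(old)

    out._backward = backward
    return out


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g.transpose(inv)

    out._backward = backward
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.grad += np.broadcast_to(g, a.shape)
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a.grad += np.broadcast_to(g, a.shape)

    out._backward = backward
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul_const(tsum(a, axis, keepdims), 1.0 / n)


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * (a.data > 0)

    out._backward = backward
    return out


def gelu(a: Tensor) -> Tensor:
    """tanh-approximation GELU."""
    c = np.float32(np.sqrt(2.0 / np.pi))
    x = a.data
    inner = c * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out = Tensor(0.5 * x * (1.0 + t), parents=(a,))

    def backward(g):
        if a.requires_grad:
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            a.grad += g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner)

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * s * (1.0 - s)

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a.grad += s * (g - dot)

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a.grad += _unbroadcast(ga, a.shape)
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b.grad += _unbroadcast(gb, b.shape)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable)."""
    z = logits.data.ravel()
    y = np.asarray(targets, dtype=np.float32).ravel()
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits.grad += (g * (p - y) / len(y)).reshape(logits.shape)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# 3D convolution and pooling
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int, out_sp: tuple[int, int, int]) -> np.ndarray:
    n, c = xp.shape[:2]
    do, ho, wo = out_sp
    cols = np.empty((n, c, k, k, k, do, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[:, :, i, j, l] = xp[
                    :,
                    :,
                    i : i + do * stride : stride,
                    j : j + ho * stride : stride,
                    l : l + wo * stride : stride,
                ]
    return cols.reshape(n, c * k**3, do * ho * wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution; ``w`` has shape (F, C, k, k, k), cubic kernels only."""
    n, c, d, h, ww = x.shape
    f, c2, k = w.shape[0], w.shape[1], w.shape[2]
    assert c == c2, (c, c2)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((padding, padding),) * 3) if padding else x.data
    out_sp = tuple((s + 2 * padding - k) // stride + 1 for s in (d, h, ww))
    cols = _im2col(xp, k, stride, out_sp)
    wflat = w.data.reshape(f, -1)
    res = np.einsum("fc,ncl->nfl", wflat, cols, optimize=True)
    if b is not None:
        res = res + b.data.reshape(1, f, 1)
    out = Tensor(res.reshape(n, f, *out_sp), parents=(x, w) + ((b,) if b is not None else ()))

    def backward(g):
        gl = g.reshape(n, f, -1)
        if w.requires_grad:
            w.grad += np.einsum("nfl,ncl->fc", gl, cols, optimize=True).reshape(w.shape)
        if b is not None and b.requires_grad:
            b.grad += gl.sum(axis=(0, 2))
        if x.requires_grad:
            dcols = np.einsum("fc,nfl->ncl", wflat, gl, optimize=True)
            dcols = dcols.reshape(n, c, k, k, k, *out_sp)
            dxp = np.zeros_like(xp)
            do, ho, wo = out_sp
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        dxp[
                            :,
                            :,
                            i : i + do * stride : stride,
                            j : j + ho * stride : stride,
                            l : l + wo * stride : stride,
                        ] += dcols[:, :, i, j, l]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x.grad += dxp

    out._backward = backward
    return out


def avgpool3d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling; spatial dims must be divisible."""
    n, c, d, h, w = x.shape
    f = factor
    assert d % f == 0 and h % f == 0 and w % f == 0, (x.shape, f)
    view = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f)
    out = Tensor(view.mean(axis=(3, 5, 7)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            gexp = np.repeat(np.repeat(np.repeat(g, f, axis=2), f, axis=3), f, axis=4)
            x.grad += gexp / f**3

    out._backward = backward
    return out
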