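"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based scalar-output autodiff engine sized for the small 3-D
networks this package trains on a single CPU.  Tensors wrap numpy
arrays; operations build a DAG; ``Tensor.backward()`` runs reverse-mode
accumulation in topological order.  Only the operations the fusion
network needs are implemented: broadcast arithmetic, matmul, the usual
pointwise nonlinearities, reductions, reshape/concat, stable
log-softmax, 3-D convolution (stride 1, 'same' padding, via im2col),
factor-2 average pooling and nearest-neighbour upsampling.

Gradients are accumulated on every node created with
``requires_grad=True`` *and* on intermediate nodes, which is what
Grad-CAM needs to read activations' gradients.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- graph mechanics ------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep at 3 conv scales
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out._backward = _bw
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = _bw
    return out


# -- pointwise nonlinearities ------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))

    def _bw(g):
        a._accum(g * (a.data > 0))

    out._backward = _bw
    return out


def leaky_relu(a: Tensor, slope: float = 0.05) -> Tensor:
    """ReLU with a small negative-side slope; immune to dead units."""
    a = as_tensor(a)
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), _parents=(a,))

    def _bw(g):
        a._accum(g * np.where(a.data > 0, 1.0, slope))

    out._backward = _bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    out = Tensor(s, _parents=(a,))

    def _bw(g):
        a._accum(g * s * (1.0 - s))

    out._backward = _bw
    return out


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.data)
    out = Tensor(t, _parents=(a,))

    def _bw(g):
        a._accum(g * (1.0 - t * t))

    out._backward = _bw
    return out


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), _parents=(a,))

    def _bw(g):
        a._accum(g / a.data)

    out._backward = _bw
    return out


# -- reductions & shape ------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def _bw(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
            return
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.data.shape))

    out._backward = _bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def _bw(g):
        a._accum(g.reshape(a.data.shape))

    out._backward = _bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + n)
                t._accum(g[tuple(idx)])
            start += n

    out._backward = _bw
    return out


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    out = Tensor(out_data, _parents=(a,))
    p = np.exp(out_data)

    def _bw(g):
        a._accum(g - p * g.sum(axis=axis, keepdims=True))

    out._backward = _bw
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    ls = log_softmax(a, axis=axis)
    out = Tensor(np.exp(ls.data), _parents=(ls,))

    def _bw(g):
        ls._accum(g * out.data)

    out._backward = _bw
    return out


# -- 3-D convolution ----------------------------------------------------

def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 'same' 3-D convolution via shift-and-matmul.

    x: (N, C_in, D, H, W); weight: (C_out, C_in, k, k, k); bias: (C_out,).
    The k^3 kernel offsets are applied as shifted views of the padded
    input, each contracted over channels with one batched matmul — much
    cheaper on CPU than materializing im2col patch matrices.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    N, C_in, D, H, W = x.data.shape
    C_out, _, k, _, _ = weight.data.shape
    pad = k // 2
    V = D * H * W
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    shifted = []  # contiguous (N, C_in, V) views per offset, kept for backward
    y = np.zeros((N, C_out, V), dtype=x.data.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, a:a + D, b:b + H, c:c + W]).reshape(N, C_in, V)
                shifted.append(xs)
                y += np.matmul(weight.data[:, :, a, b, c], xs)
    y += bias.data[None, :, None]
    out = Tensor(y.reshape(N, C_out, D, H, W), _parents=(x, weight, bias))

    def _bw(g):
        gy = g.reshape(N, C_out, V)
        if bias.requires_grad:
            bias._accum(gy.sum(axis=(0, 2)))
        dw = np.zeros_like(weight.data) if weight.requires_grad else None
        dxp = (np.zeros((N, C_in, D + 2 * pad, H + 2 * pad, W + 2 * pad),
                        dtype=x.data.dtype) if x.requires_grad else None)
        gy_m = gy.transpose(1, 0, 2).reshape(C_out, N * V)
        idx = 0
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = shifted[idx]
                    idx += 1
                    if dw is not None:
                        xs_m = xs.transpose(1, 0, 2).reshape(C_in, N * V)
                        dw[:, :, a, b, c] = gy_m @ xs_m.T
                    if dxp is not None:
                        dxs = np.matmul(weight.data[:, :, a, b, c].T, gy)
                        dxp[:, :, a:a + D, b:b + H, c:c + W] += \
                            dxs.reshape(N, C_in, D, H, W)
        if dw is not None:
            weight._accum(dw)
        if dxp is not None:
            x._accum(dxp[:, :, pad:pad + D, pad:pad + H, pad:pad + W])

    out._backward = _bw
    return out


def avgpool3d(x: Tensor) -> Tensor:
    """Factor-2 average pooling over the three spatial axes of (N,C,D,H,W)."""
    x = as_tensor(x)
    N, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"avgpool3d requires even spatial dims, got {(D, H, W)}")
    v = x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = Tensor(v.mean(axis=(3, 5, 7)), _parents=(x,))

    def _bw(g):
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        x._accum(gx)

    out._backward = _bw
    return out


def upsample3d(x: Tensor) -> Tensor:
    """Factor-2 nearest-neighbour upsampling over the spatial axes."""
    x = as_tensor(x)
    up = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)
    out = Tensor(up, _parents=(x,))

    def _bw(g):
        N, C, D, H, W = x.data.shape
        v = g.reshape(N, C, D, 2, H, 2, W, 2)
        x._accum(v.sum(axis=(3, 5, 7)))

    out._backward = _bw
    return out
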