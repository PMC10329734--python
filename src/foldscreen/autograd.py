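"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's contact-map predictor is trained, and its gradient-based
attribution maps are computed, through this small tape-based engine.  A
:class:`Tensor` wraps an ``ndarray`` and remembers the operation that
produced it; calling :meth:`Tensor.backward` on a scalar loss propagates
gradients to every tensor in the graph, including intermediate layer
activations (needed for regional activation mapping).

Only the operations the model requires are implemented: broadcasting
arithmetic, batched matrix products, ReLU, softmax, reductions, shape
manipulation, strided/dilated 1D and 2D convolution (as a tap loop of
channel matmuls, which keeps memory linear in the input), and a gather
used by the relative-position attention term.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context in which operations do not build the autodiff graph."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
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
        self.grad = _accum(self.grad, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free closure references once consumed to bound memory
            node._backward = None
            node._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # keep python scalars at single precision so float32 graphs do not
        # silently promote to float64 (float64 operands still win promotion)
        return Tensor(np.asarray(x, dtype=np.float32))
    return Tensor(np.asarray(x))


def _accum(current, update):
    if current is None:
        return update.copy() if isinstance(update, np.ndarray) else np.asarray(update)
    current += update
    return current


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents: Iterable[Tensor], backward):
    parents = [p for p in parents if isinstance(p, Tensor)]
    if grad_enabled() and parents:
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- elementwise / arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        a.grad = _accum(a.grad, _unbroadcast(g, a.data.shape))
        b.grad = _accum(b.grad, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        a.grad = _accum(a.grad, _unbroadcast(g * b.data, a.data.shape))
        b.grad = _accum(b.grad, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        a.grad = _accum(a.grad, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a.grad = _accum(a.grad, g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a.grad = _accum(a.grad, g / a.data)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a.grad = _accum(a.grad, g * mask)

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        # dL/dx = s * (g - sum(g*s))
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a.grad = _accum(a.grad, out_data * (g - dot))

    return _make(out_data, (a,), backward)


# -- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            grad = np.broadcast_to(g, a.data.shape)
        a.grad = _accum(a.grad, grad.astype(a.data.dtype, copy=True))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


# -- shape manipulation ------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a.grad = _accum(a.grad, g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = astensor(a)
    out_data = a.data.transpose(axes)

    def backward(g):
        inv = None if axes is None else np.argsort(axes)
        a.grad = _accum(a.grad, np.ascontiguousarray(g.transpose(inv)))

    return _make(out_data, (a,), backward)


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    out_data = np.broadcast_to(a.data, shape)

    def backward(g):
        a.grad = _accum(a.grad, _unbroadcast(g, a.data.shape))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.grad = _accum(t.grad, g[tuple(idx)])

    return _make(out_data, tensors, backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad, idx, g)
        a.grad = _accum(a.grad, grad)

    return _make(out_data, (a,), backward)


def rel_gather(a, idx: np.ndarray) -> Tensor:
    """Gather ``a[..., i, idx[i, j]] -> out[..., i, j]`` along the last axis.

    Used to skew query-by-relative-embedding logits into absolute (i, j)
    position; ``idx`` has shape (L, L) with entries indexing the relative
    offset axis of ``a`` (shape (..., L, R)).
    """
    a = astensor(a)
    L = idx.shape[0]
    rows = np.arange(L)[:, None]
    out_data = a.data[..., rows, idx]

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad.reshape(-1, *a.data.shape[-2:]),
                  (slice(None), rows, idx),
                  g.reshape(-1, L, idx.shape[1]))
        a.grad = _accum(a.grad, grad)

    return _make(out_data, (a,), backward)


# -- linear algebra ----------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        # batched matmul broadcasts leading axes; fold them back
        a.grad = _accum(a.grad, _unbroadcast(ga, a.data.shape))
        b.grad = _accum(b.grad, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def batch_norm(x, gamma, beta, axes: tuple, eps: float,
               mean=None, var=None, stats_out: list = None) -> Tensor:
    """Fused batch normalization.

    With ``mean``/``var`` given (evaluation mode) they are treated as
    constants; otherwise batch statistics over ``axes`` are used and
    differentiated through.  ``gamma``/``beta`` are per-channel tensors
    already shaped to broadcast.  Fusing keeps one full-size temporary
    instead of the half-dozen a composed implementation retains, which
    matters for cache/allocator behaviour on long convolutional stacks.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    frozen = mean is not None
    if frozen:
        mu, v = np.asarray(mean), np.asarray(var)
    else:
        mu = x.data.mean(axis=axes, keepdims=True)
        v = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gamma.grad = _accum(gamma.grad, (g * xhat).sum(
            axis=axes, keepdims=True).reshape(gamma.data.shape))
        beta.grad = _accum(beta.grad, g.sum(
            axis=axes, keepdims=True).reshape(beta.data.shape))
        if frozen:
            x.grad = _accum(x.grad, g * (gamma.data * inv))
        else:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x.grad = _accum(x.grad, inv * (dxhat - m1 - xhat * m2))

    if stats_out is not None and not frozen:
        stats_out.append((mu, v))
    return _make(out_data, (x, gamma, beta), backward)


# -- convolution -------------------------------------------------------------

def conv1d(x, w, b=None, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """1D convolution. x: (N, Cin, L); w: (Cout, Cin, K); b: (Cout,)."""
    x, w = astensor(x), astensor(w)
    b = astensor(b) if b is not None else None
    N, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    if padding:
        xp = np.zeros((N, Cin, L + 2 * padding), dtype=x.data.dtype)
        xp[:, :, padding:padding + L] = x.data
    else:
        xp = x.data
    Lp = xp.shape[2]
    Lout = (Lp - (K - 1) * dilation - 1) // stride + 1
    out_data = np.zeros((N, Cout, Lout), dtype=x.data.dtype)
    taps = []
    for k in range(K):
        start = k * dilation
        sl = xp[:, :, start:start + stride * (Lout - 1) + 1:stride]
        taps.append((start, sl))
        out_data += np.matmul(w.data[:, :, k], sl)
    if b is not None:
        out_data += b.data[None, :, None]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k, (start, sl) in enumerate(taps):
            gw[:, :, k] = np.tensordot(g, sl, axes=([0, 2], [0, 2]))
            gxp[:, :, start:start + stride * (Lout - 1) + 1:stride] += np.matmul(
                w.data[:, :, k].T, g)
        if padding:
            gxp = gxp[:, :, padding:Lp - padding]
        x.grad = _accum(x.grad, gxp)
        w.grad = _accum(w.grad, gw)
        if b is not None:
            b.grad = _accum(b.grad, g.sum(axis=(0, 2)))

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out_data, parents, backward)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2D convolution. x: (N, Cin, H, W); w: (Cout, Cin, KH, KW)."""
    x, w = astensor(x), astensor(w)
    b = astensor(b) if b is not None else None
    N, Cin, H, W = x.data.shape
    Cout, _, KH, KW = w.data.shape
    if padding:
        xp = np.zeros((N, Cin, H + 2 * padding, W + 2 * padding), dtype=x.data.dtype)
        xp[:, :, padding:padding + H, padding:padding + W] = x.data
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Hout = (Hp - (KH - 1) * dilation - 1) // stride + 1
    Wout = (Wp - (KW - 1) * dilation - 1) // stride + 1
    K2 = KH * KW
    taps = [(kh * dilation, kw * dilation) for kh in range(KH) for kw in range(KW)]
    # im2col: one contiguous (N, K2*Cin, Hout*Wout) buffer, one GEMM
    cols = np.empty((N, K2 * Cin, Hout * Wout), dtype=x.data.dtype)
    for t, (hs, ws) in enumerate(taps):
        sl = xp[:, :, hs:hs + stride * (Hout - 1) + 1:stride,
                ws:ws + stride * (Wout - 1) + 1:stride]
        cols[:, t * Cin:(t + 1) * Cin, :] = sl.reshape(N, Cin, -1)
    w_flat = np.ascontiguousarray(
        w.data.transpose(0, 2, 3, 1).reshape(Cout, K2 * Cin))
    out = np.matmul(w_flat, cols).reshape(N, Cout, Hout, Wout)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gf = g.reshape(N, Cout, -1)
        gw_flat = np.tensordot(gf, cols, axes=([0, 2], [0, 2]))
        gw = gw_flat.reshape(Cout, KH, KW, Cin).transpose(0, 3, 1, 2)
        gcols = np.matmul(w_flat.T, gf)            # (N, K2*Cin, Hout*Wout)
        gxp = np.zeros_like(xp)
        for t, (hs, ws) in enumerate(taps):
            gxp[:, :, hs:hs + stride * (Hout - 1) + 1:stride,
                ws:ws + stride * (Wout - 1) + 1:stride] += \
                gcols[:, t * Cin:(t + 1) * Cin, :].reshape(N, Cin, Hout, Wout)
        if padding:
            gxp = gxp[:, :, padding:Hp - padding, padding:Wp - padding]
        x.grad = _accum(x.grad, gxp)
        w.grad = _accum(w.grad, np.ascontiguousarray(gw))
        if b is not None:
            b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, backward)
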