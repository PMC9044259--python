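"""Compact reverse-mode automatic differentiation over NumPy arrays.

The detector is trained with gradient descent, so every forward operation
used inside the network records a vector-Jacobian product (VJP) on a tape.
Calling :meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients into the leaf tensors that were
created with ``requires_grad=True``.

The op set is deliberately small: elementwise arithmetic, a handful of
transcendentals, reductions, reshaping/indexing, (grouped) 2-D convolution,
nearest-neighbour upsampling, softmax and a fused binary cross-entropy.
That is exactly what a single-stage convolutional detector needs; nothing
speculative is included.

Arrays keep the dtype they come in with (float32 throughout the network;
float64 in the numerical-gradient test-bench).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable tape recording (inference / target construction)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A NumPy array plus an optional gradient and tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` into all requiring leaves.

        The graph is freed as it is consumed; a second backward pass
        requires a fresh forward pass.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient argument "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs are deep for big images)
        topo: list[Tensor] = []
        state: dict[int, int] = {}
        stack: list[Tensor] = [self]
        while stack:
            node = stack[-1]
            nid = id(node)
            if state.get(nid, 0) == 0:
                state[nid] = 1
                for p in node._parents:
                    if p.requires_grad and state.get(id(p), 0) == 0:
                        stack.append(p)
            else:
                stack.pop()
                if state[nid] == 1:
                    state[nid] = 2
                    topo.append(node)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is None:
                continue
            grads = node._vjp(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g
            # free graph memory eagerly
            node._parents = ()
            node._vjp = None
            node.grad = None

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def vjp(go):
        return _unbroadcast(go, a.shape), _unbroadcast(go, b.shape)

    return _make(out, (a, b), vjp)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def vjp(go):
        return (_unbroadcast(go * b.data, a.shape),
                _unbroadcast(go * a.data, b.shape))

    return _make(out, (a, b), vjp)


def power(a, exponent: float):
    a = as_tensor(a)
    out = a.data ** exponent

    def vjp(go):
        return (go * exponent * a.data ** (exponent - 1.0),)

    return _make(out, (a,), vjp)


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)

    def vjp(go):
        return (go * out,)

    return _make(out, (a,), vjp)


def log(a):
    a = as_tensor(a)
    out = np.log(a.data)

    def vjp(go):
        return (go / a.data,)

    return _make(out, (a,), vjp)


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)

    def vjp(go):
        return (go * (0.5 / out),)

    return _make(out, (a,), vjp)


def tanh(a):
    a = as_tensor(a)
    out = np.tanh(a.data)

    def vjp(go):
        return (go * (1.0 - out * out),)

    return _make(out, (a,), vjp)


def sigmoid(a):
    a = as_tensor(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def vjp(go):
        return (go * out * (1.0 - out),)

    return _make(out, (a,), vjp)


def arctan(a):
    a = as_tensor(a)
    out = np.arctan(a.data)

    def vjp(go):
        return (go / (1.0 + a.data * a.data),)

    return _make(out, (a,), vjp)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)
    mask = a.data >= b.data  # ties route the gradient to the first argument

    def vjp(go):
        return (_unbroadcast(go * mask, a.shape),
                _unbroadcast(go * ~mask, b.shape))

    return _make(out, (a, b), vjp)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.minimum(a.data, b.data)
    mask = a.data <= b.data

    def vjp(go):
        return (_unbroadcast(go * mask, a.shape),
                _unbroadcast(go * ~mask, b.shape))

    return _make(out, (a, b), vjp)


def clip(a, lo, hi):
    return minimum(maximum(a, lo), hi)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(go):
        g = np.asarray(go)
        if not keepdims and axis is not None:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            for ax in sorted(ax % a.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.shape).astype(a.dtype, copy=False),)

    return _make(out, (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        count = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape):
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def vjp(go):
        return (go.reshape(a.shape),)

    return _make(out, (a,), vjp)


def transpose(a, axes):
    a = as_tensor(a)
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def vjp(go):
        return (go.transpose(inv),)

    return _make(out, (a,), vjp)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(go):
        return tuple(np.split(go, splits, axis=axis))

    return _make(out, tuple(tensors), vjp)


def getitem(a, idx):
    a = as_tensor(a)
    out = a.data[idx]
    fancy = isinstance(idx, (np.ndarray, list)) or (
        isinstance(idx, tuple) and any(isinstance(i, (np.ndarray, list)) for i in idx))

    def vjp(go):
        gx = np.zeros_like(a.data)
        if fancy:
            np.add.at(gx, idx, go)
        else:
            gx[idx] += go
        return (gx,)

    return _make(out, (a,), vjp)


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def vjp(go):
        pieces = np.split(go, len(tensors), axis=axis)
        return tuple(p.squeeze(axis) if p.shape != t.shape else p
                     for p, t in zip(pieces, tensors))

    return _make(out, tuple(tensors), vjp)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b):
    """Batched matrix product with broadcasting over leading axes."""
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def vjp(go):
        ga = np.matmul(go, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), go)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(out, (a, b), vjp)


def softmax(a, axis=-1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    out = ez / ez.sum(axis=axis, keepdims=True)

    def vjp(go):
        dot = (go * out).sum(axis=axis, keepdims=True)
        return (out * (go - dot),)

    return _make(out, (a,), vjp)


# ---------------------------------------------------------------------------
# convolution and friends
# ---------------------------------------------------------------------------

def _pad_hw(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """Grouped 2-D cross-correlation, NCHW layout.

    ``w`` has shape ``(C_out, C_in // groups, kh, kw)``.  Three code paths:
    a BLAS matmul for 1x1 projections, a tap-loop for depthwise kernels and
    an im2col matmul for everything else.
    """
    x, w = as_tensor(x), as_tensor(w)
    bt = as_tensor(b) if b is not None else None
    O, Cg, kh, kw = w.shape
    N, C, H, W = x.shape
    if C != Cg * groups or O % groups:
        raise ValueError("channel bookkeeping does not match groups")

    if kh == 1 and kw == 1 and groups == 1:
        out, vjp = _conv_1x1(x, w, stride)
    elif groups == C and O == C and Cg == 1:
        out, vjp = _conv_depthwise(x, w, stride, padding)
    else:
        out, vjp = _conv_general(x, w, stride, padding, groups)

    parents = [x, w]
    if bt is not None:
        out = out + bt.data.reshape(1, O, 1, 1)
        parents.append(bt)

        def vjp_b(go):
            gx, gw = vjp(go)
            return gx, gw, go.sum(axis=(0, 2, 3))

        return _make(out, parents, vjp_b)

    return _make(out, parents, vjp)


def _conv_1x1(x, w, stride):
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    N, C, H, W = xs.shape
    O = w.shape[0]
    wmat = w.data.reshape(O, C)
    xr = xs.reshape(N, C, H * W)
    out = np.matmul(wmat[None], xr).reshape(N, O, H, W)

    def vjp(go):
        gor = go.reshape(N, O, H * W)
        gw = np.matmul(gor, xr.transpose(0, 2, 1)).sum(axis=0)
        gxs = np.matmul(wmat.T[None], gor).reshape(N, C, H, W)
        if stride > 1:
            gx = np.zeros_like(x.data)
            gx[:, :, ::stride, ::stride] = gxs
        else:
            gx = gxs
        return gx, gw.reshape(w.shape)

    return out, vjp


def _conv_depthwise(x, w, stride, padding):
    xp = _pad_hw(x.data, padding)
    N, C, Hp, Wp = xp.shape
    kh, kw = w.shape[2], w.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    wd = w.data[:, 0]  # (C, kh, kw)
    out = np.zeros((N, C, OH, OW), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
            out += sl * wd[:, i, j][None, :, None, None]

    def vjp(go):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]
                gw[:, 0, i, j] = (go * sl).sum(axis=(0, 2, 3))
                gxp[:, :, i:i + stride * OH:stride,
                    j:j + stride * OW:stride] += go * wd[:, i, j][None, :, None, None]
        gx = gxp[:, :, padding:Hp - padding, padding:Wp - padding] if padding else gxp
        return gx, gw

    return out, vjp


def _conv_general(x, w, stride, padding, groups):
    xp = _pad_hw(x.data, padding)
    N, C, Hp, Wp = xp.shape
    O, Cg, kh, kw = w.shape
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    Og = O // groups
    outs = []
    cols_per_group = []
    for g in range(groups):
        xg = xp[:, g * Cg:(g + 1) * Cg]
        win = sliding_window_view(xg, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N, OH * OW, Cg * kh * kw)
        wmat = w.data[g * Og:(g + 1) * Og].reshape(Og, Cg * kh * kw)
        og = np.matmul(cols, wmat.T).transpose(0, 2, 1).reshape(N, Og, OH, OW)
        outs.append(og)
        cols_per_group.append(cols)
    out = outs[0] if groups == 1 else np.concatenate(outs, axis=1)

    def vjp(go):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for g in range(groups):
            gog = go[:, g * Og:(g + 1) * Og].reshape(N, Og, OH * OW)
            cols = cols_per_group[g]
            wmat = w.data[g * Og:(g + 1) * Og].reshape(Og, Cg * kh * kw)
            gw[g * Og:(g + 1) * Og] = np.matmul(
                gog, cols).sum(axis=0).reshape(Og, Cg, kh, kw)
            gcols = np.matmul(gog.transpose(0, 2, 1), wmat)  # (N, L, Cg*kh*kw)
            gcols = gcols.reshape(N, OH, OW, Cg, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, g * Cg:(g + 1) * Cg,
                        i:i + stride * OH:stride,
                        j:j + stride * OW:stride] += gcols[:, :, :, :, i, j]
        gx = gxp[:, :, padding:Hp - padding, padding:Wp - padding] if padding else gxp
        return gx, gw

    return out, vjp


def upsample_nearest2x(x):
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def vjp(go):
        return (go.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return _make(out, (x,), vjp)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits, targets, reduction: str = "mean"):
    """Numerically stable sigmoid + binary cross-entropy.

    ``targets`` is a constant array of the same shape as ``logits``.
    """
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=logits.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "mean":
        out = loss.mean()
        scale = 1.0 / loss.size
    elif reduction == "sum":
        out = loss.sum()
        scale = 1.0
    elif reduction == "none":
        out = loss
        scale = 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def vjp(go):
        s = np.empty_like(z)
        pos = z >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        s[~pos] = ez / (1.0 + ez)
        return (go * scale * (s - t),)

    return _make(out, (logits,), vjp)
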