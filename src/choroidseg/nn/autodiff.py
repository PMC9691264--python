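"""Minimal reverse-mode automatic differentiation on numpy arrays.

A define-by-run tape in the micrograd style, generalized to ndarrays and to
the handful of operations a small convolutional encoder-decoder needs:
broadcast arithmetic, matmul, stride-1 dilated conv2d (accumulated over
kernel taps as one BLAS matmul per tap, forward and backward), 2x2 max
pooling with first-occurrence argmax, nearest-neighbour upsampling,
concatenation, reductions, and the pointwise functions (exp, log, sqrt,
abs, relu, logistic).

Backward closures deliberately never capture their output tensor, so graphs
are reference-cycle-free and freed by reference counting as soon as the
loss goes out of scope.

All data is float32.  Gradient correctness is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "upsample2x2", "conv1d_channels"]


def _f32(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.shape))

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.sign(self.data)
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (self.data > 0)
        )
        return out

    def sigmoid(self):
        s = expit(self.data)
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * s * (1.0 - s)
        )
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; the gradient passes through unclipped entries only."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    out[:, :, pad:-pad, pad:-pad] = x
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 2-D correlation with 'same' zero padding (spatial size kept).

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw) with odd kh == kw;
    effective padding is ``dilation * (k - 1) / 2``.  The correlation is
    accumulated over kernel offsets — one (Cout, Cin) x (N, Cin, H*W)
    matmul per tap — which keeps every copy a plain slice copy.
    """
    cout, cin, kh, kw = w.shape
    if kh != kw or kh % 2 == 0:
        raise ValueError("square odd kernels only")
    if np.any(~np.isfinite(x.data)):
        raise ValueError("conv2d received non-finite input")
    pad = dilation * (kh - 1) // 2
    n, _, h, wid = x.shape
    L = h * wid
    xpad = _pad2d(x.data, pad)
    y = None
    for ki in range(kh):
        for kj in range(kw):
            i0, j0 = ki * dilation, kj * dilation
            xs = xpad[:, :, i0:i0 + h, j0:j0 + wid].reshape(n, cin, L)
            t = np.matmul(w.data[:, :, ki, kj][None], xs)
            y = t if y is None else y + t
    y = y.reshape(n, cout, h, wid)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _prev=prev)

    def bw(g):
        gflat = g.reshape(n, cout, L)
        need_dx = x.requires_grad
        dxpad = np.zeros_like(xpad) if need_dx else None
        if w.requires_grad:
            dw = np.empty_like(w.data)
        for ki in range(kh):
            for kj in range(kw):
                i0, j0 = ki * dilation, kj * dilation
                if w.requires_grad:
                    xs = xpad[:, :, i0:i0 + h, j0:j0 + wid].reshape(n, cin, L)
                    dw[:, :, ki, kj] = np.matmul(
                        gflat, xs.transpose(0, 2, 1)).sum(axis=0)
                if need_dx:
                    dxs = np.matmul(w.data[:, :, ki, kj].T[None], gflat)
                    dxpad[:, :, i0:i0 + h, j0:j0 + wid] += dxs.reshape(
                        n, cin, h, wid)
        if w.requires_grad:
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if need_dx:
            x._accum(dxpad[:, :, pad:pad + h, pad:pad + wid] if pad else dxpad)

    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route the gradient to the first
    element of the window."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial size")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, w))

    out._backward = bw
    return out


def upsample2x2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def conv1d_channels(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Kernel-3, zero-padded 1-D convolution along the last axis of (N, C).

    Used by the channel-enhancement branch on pooled channel statistics, so
    the output length equals the channel count.
    """
    if w.shape != (3,):
        raise ValueError("conv1d_channels expects a length-3 kernel")
    xp = np.pad(x.data, ((0, 0), (1, 1)))
    y = (w.data[0] * xp[:, :-2] + w.data[1] * xp[:, 1:-1] + w.data[2] * xp[:, 2:])
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _prev=prev)

    def bw(g):
        if w.requires_grad:
            w._accum(np.array(
                [(g * xp[:, :-2]).sum(), (g * xp[:, 1:-1]).sum(),
                 (g * xp[:, 2:]).sum()], dtype=np.float32))
        if b is not None and b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (1, 1)))
            x._accum(w.data[0] * gp[:, 2:] + w.data[1] * gp[:, 1:-1]
                     + w.data[2] * gp[:, :-2])

    out._backward = bw
    return out
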