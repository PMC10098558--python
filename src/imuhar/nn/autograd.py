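"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the small set of differentiable primitives needed by
the sensor-encoder and time-series architectures in this package: dense and
(dilated/strided) convolutional layers via ``unfold``, the gating
nonlinearities of recurrent and WaveNet blocks, and a fused
softmax/cross-entropy loss.  Gradients are accumulated by topological
traversal of the recorded operation graph.

All arrays are float64.  Randomness (dropout masks, initialization) lives
outside this module; masks enter the graph as constants.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "matmul",
    "pad1d",
    "pad2d",
    "softmax",
    "softmax_cross_entropy",
    "unfold1d",
    "unfold2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        # most nodes receive exactly one contribution; copy instead of
        # zero-fill + add
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw if req else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if req else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

            out._backward = bw
        return out

    def flip(self, axis: int):
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(None, None, -1)
        sl = tuple(sl)
        out = Tensor(self.data[sl], self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g[sl])
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if self.requires_grad:

            def bw(g):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------
    # nonlinearities
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def leaky_relu(self, negative_slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, negative_slope)
        out = Tensor(self.data * factor, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * factor)
        return out


# ----------------------------------------------------------------------
def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting on leading dimensions."""
    req = a.requires_grad or b.requires_grad
    out = Tensor(np.matmul(a.data, b.data), req, (a, b))

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = bw if req else None
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))

    def bw(g):
        sizes = [t.data.shape[axis] for t in tensors]
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw if req else None
    return out


def pad1d(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad the last axis of (N, C, T)."""
    if left == 0 and right == 0:
        return x
    width = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    out = Tensor(np.pad(x.data, width), x.requires_grad, (x,))
    if x.requires_grad:
        sl = (Ellipsis, slice(left, left + x.data.shape[-1]))
        out._backward = lambda g: x._accum(g[sl])
    return out


def pad2d(x: Tensor, ph: tuple[int, int], pw: tuple[int, int]) -> Tensor:
    """Zero-pad the last two axes of (N, C, H, W)."""
    if ph == (0, 0) and pw == (0, 0):
        return x
    width = [(0, 0)] * (x.ndim - 2) + [ph, pw]
    out = Tensor(np.pad(x.data, width), x.requires_grad, (x,))
    if x.requires_grad:
        h, w = x.data.shape[-2], x.data.shape[-1]
        sl = (Ellipsis, slice(ph[0], ph[0] + h), slice(pw[0], pw[0] + w))
        out._backward = lambda g: x._accum(g[sl])
    return out


def unfold1d(x: Tensor, kernel: int, stride: int = 1, dilation: int = 1) -> Tensor:
    """Extract sliding patches from (N, C, T) -> (N, C*kernel, L).

    Column l holds the receptive field starting at ``l*stride`` with taps
    spaced ``dilation`` samples apart; this is the im2col step that turns a
    1-D convolution into a matrix product.
    """
    n, c, t = x.data.shape
    span = (kernel - 1) * dilation + 1
    length = (t - span) // stride + 1
    if length <= 0:
        raise ValueError(f"input length {t} too short for kernel span {span}")
    idx = stride * np.arange(length)[None, :] + dilation * np.arange(kernel)[:, None]  # (k, L)
    patches = x.data[:, :, idx]  # (N, C, k, L)
    out = Tensor(patches.reshape(n, c * kernel, length), x.requires_grad, (x,))

    if x.requires_grad:

        def bw(g):
            gp = g.reshape(n, c, kernel, length)
            gx = np.zeros_like(x.data)
            # Per-tap strided adds: within one tap j the write targets are
            # disjoint, so plain slice += is safe (and much faster than a
            # scatter).
            for j in range(kernel):
                start = j * dilation
                gx[:, :, start : start + stride * length : stride] += gp[:, :, j, :]
            x._accum(gx)

        out._backward = bw
    return out


def unfold2d(x: Tensor, kernel: tuple[int, int], stride: tuple[int, int]) -> Tensor:
    """Extract sliding patches from (N, C, H, W) -> (N, C*kh*kw, Hout*Wout)."""
    n, c, h, w = x.data.shape
    kh, kw = kernel
    sh, sw = stride
    hout = (h - kh) // sh + 1
    wout = (w - kw) // sw + 1
    if hout <= 0 or wout <= 0:
        raise ValueError(f"input ({h},{w}) too small for kernel {kernel}")
    ih = sh * np.arange(hout)[None, :] + np.arange(kh)[:, None]  # (kh, Hout)
    iw = sw * np.arange(wout)[None, :] + np.arange(kw)[:, None]  # (kw, Wout)
    # (N, C, kh, Hout, kw, Wout)
    patches = x.data[:, :, ih[:, :, None, None], iw[None, None, :, :]]
    out = Tensor(
        patches.transpose(0, 1, 2, 4, 3, 5).reshape(n, c * kh * kw, hout * wout),
        x.requires_grad,
        (x,),
    )

    if x.requires_grad:

        def bw(g):
            gp = g.reshape(n, c, kh, kw, hout, wout)
            gx = np.zeros_like(x.data)
            for jh in range(kh):
                for jw in range(kw):
                    gx[
                        :,
                        :,
                        jh : jh + sh * hout : sh,
                        jw : jw + sw * wout : sw,
                    ] += gp[:, :, jh, jw, :, :]
            x._accum(gx)

        out._backward = bw
    return out


# ----------------------------------------------------------------------
def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain ndarray softmax (inference path; no gradient)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between row-softmax of ``logits`` and target rows.

    ``targets`` may be one-hot or soft probability rows; it enters the graph
    as a constant.
    """
    t = np.asarray(targets, dtype=np.float64)
    p = softmax(logits.data, axis=-1)
    n = logits.data.shape[0]
    eps = 1e-12
    loss_val = -(t * np.log(p + eps)).sum() / n
    out = Tensor(loss_val, logits.requires_grad, (logits,))
    if logits.requires_grad:
        out._backward = lambda g: logits._accum(g * (p - t) / n)
    return out
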