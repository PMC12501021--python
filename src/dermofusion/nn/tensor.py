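"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with a gradient slot and a
closure that propagates gradients to its parents.  The op set is exactly what
the models in this package need: broadcasting arithmetic, matmul, reductions,
shape ops, ReLU/GELU, exp/log/sqrt, 2-D convolution and pooling.  Everything
is computed in float64; graphs are built eagerly and freed after
:meth:`Tensor.backward`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph memory as we go
            node._backward = None
            node._prev = ()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data
        a_vec = self.data.ndim == 1
        b_vec = other.data.ndim == 1

        def bwd(g):
            a, b = self.data, other.data
            if a_vec and b_vec:  # dot product
                ga, gb = g * b, g * a
            elif a_vec:          # (k,) @ (..., k, n) -> (..., n)
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.multiply.outer(a, g) if b.ndim == 2 else None
                if gb is None:
                    gb = a[:, None] * np.expand_dims(g, -2)
            elif b_vec:          # (..., m, k) @ (k,) -> (..., m)
                ga = np.expand_dims(g, -1) * b
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim == 2 else (
                    np.expand_dims(g, -1) * a).sum(axis=tuple(range(a.ndim - 1)))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            if self.requires_grad:
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def gelu(self):
        """Exact Gaussian-CDF GELU: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (phi + x * pdf))

        return Tensor._make(x * phi, (self,), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Plain-numpy max, used for numerically stable softmax shifts."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # --------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    @staticmethod
    def concat(tensors: Iterable["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [_as_tensor(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        return Tensor._make(out_data, tuple(tensors), bwd)

    # ------------------------------------------------------------ conv / pool
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """NCHW x (O,I,kh,kw) -> NCHW convolution (cross-correlation)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, weight {ci}")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                       mode="constant")
        hp, wp = x.shape[2], x.shape[3]
        oh = (hp - kh) // stride + 1
        ow = (wp - kw) // stride + 1
        sn, sc, sh, sw = x.strides
        cols = as_strided(
            x,
            shape=(n, c, kh, kw, oh, ow),
            strides=(sn, sc, sh, sw, sh * stride, sw * stride),
            writeable=False,
        )
        cols2 = cols.reshape(n, c * kh * kw, oh * ow)
        wmat = w.reshape(o, c * kh * kw)
        out_data = (wmat @ cols2).reshape(n, o, oh, ow)

        x_padded_shape = x.shape

        def bwd(g):
            gmat = g.reshape(n, o, oh * ow)
            if weight.requires_grad:
                # (o, ckk) = sum_n (o, L) @ (L, ckk)
                gw = np.einsum("nol,ncl->oc", gmat, cols2).reshape(w.shape)
                weight._accumulate(gw)
            if self.requires_grad:
                gcols = np.einsum("oc,nol->ncl", wmat, gmat)
                gcols = gcols.reshape(n, c, kh, kw, oh, ow)
                gx = np.zeros(x_padded_shape, dtype=float)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + oh * stride : stride,
                           j : j + ow * stride : stride] += gcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:-padding or None, padding:-padding or None]
                self._accumulate(gx)

        return Tensor._make(out_data, (self, weight), bwd)

    def avg_pool2d(self, k: int, stride: int | None = None) -> "Tensor":
        stride = stride or k
        n, c, h, w = self.shape
        oh = (h - k) // stride + 1
        ow = (w - k) // stride + 1
        sn, sc, sh, sw = self.data.strides
        win = as_strided(self.data, (n, c, oh, ow, k, k),
                         (sn, sc, sh * stride, sw * stride, sh, sw), writeable=False)
        out_data = win.mean(axis=(4, 5))

        def bwd(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            gk = g / (k * k)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i : i + oh * stride : stride,
                       j : j + ow * stride : stride] += gk
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bwd)

    def max_pool2d(self, k: int, stride: int | None = None,
                   padding: int = 0) -> "Tensor":
        stride = stride or k
        x = self.data
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                       mode="constant", constant_values=-np.inf)
        n, c, h, w = x.shape
        oh = (h - k) // stride + 1
        ow = (w - k) // stride + 1
        sn, sc, sh, sw = x.strides
        win = as_strided(x, (n, c, oh, ow, k, k),
                         (sn, sc, sh * stride, sw * stride, sh, sw), writeable=False)
        flat = win.reshape(n, c, oh, ow, k * k)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bwd(g):
            if not self.requires_grad:
                return
            gx = np.zeros((n, c, h, w), dtype=float)
            ii, jj = np.divmod(arg, k)
            ni, ci_, oi, oj = np.indices(arg.shape)
            rows = oi * stride + ii
            cols_ = oj * stride + jj
            np.add.at(gx, (ni, ci_, rows, cols_), g)
            if padding:
                gx = gx[:, :, padding:-padding or None, padding:-padding or None]
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bwd)


# ----------------------------------------------------------------- functional
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max_detached(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max_detached(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy for integer labels; logits (N, K)."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()
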