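"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a node with a
closure that maps the output gradient to parent gradients, and
:meth:`Tensor.backward` runs the tape in reverse topological order.  float32
throughout.  The op set is exactly what the segmentation network needs
(dense/attention algebra, window rearrangements via reshape/transpose/roll,
3x3 convolutions as nine shifted matmuls, bilinear up/down-sampling as fixed
linear maps) — not a general framework.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special

__all__ = [
    "Tensor",
    "concat",
    "split",
    "matmul",
    "softmax",
    "layer_norm",
    "gelu",
    "relu",
    "hypot",
    "pad_reflect",
    "pad_zero",
    "roll",
    "take_rows",
    "upsample2d",
]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _F32:
        a = a.astype(_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array plus (optionally) a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here are deep (many blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go; parameters keep their grads
                node._backward = None
                node._parents = ()

    # -- graph construction helper ----------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros(self.shape, dtype=_F32)
            full[idx] = g  # basic (non-repeating) indexing only
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(_F32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(_F32))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims, dtype=_F32), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g / (2.0 * np.maximum(out_data, 1e-12)))

        return Tensor._make(out_data, (self,), bw)


# -- free functions ---------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(lo), int(hi))
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


def split(t: Tensor, sections: int, axis: int = 0) -> list[Tensor]:
    """Split into `sections` equal chunks along `axis`."""
    chunks = np.split(t.data, sections, axis=axis)
    outs = []
    step = t.shape[axis] // sections
    for i, c in enumerate(chunks):
        lo = i * step

        def bw(g, lo=lo):
            full = np.zeros(t.shape, dtype=_F32)
            idx = [slice(None)] * t.ndim
            idx[axis] = slice(lo, lo + step)
            full[tuple(idx)] = g
            t._accumulate(full)

        outs.append(Tensor._make(c, (t,), bw))
    return outs


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    x = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        t._accumulate(s * (g - dot))

    return Tensor._make(s, (t,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True, dtype=_F32)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True, dtype=_F32)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def bw(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=axes).astype(_F32))
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accumulate(g.sum(axis=axes).astype(_F32))
        if x.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True, dtype=_F32)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True, dtype=_F32)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), bw)


def gelu(t: Tensor) -> Tensor:
    x = t.data
    cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0, dtype=_F32)))
    out = x * cdf

    def bw(g):
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        t._accumulate(g * (cdf + x * pdf).astype(_F32))

    return Tensor._make(out, (t,), bw)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def bw(g):
        t._accumulate(g * mask)

    return Tensor._make(t.data * mask, (t,), bw)


def hypot(a: Tensor, b: Tensor) -> Tensor:
    """sqrt(a^2 + b^2) with a bounded gradient at the origin."""
    out_data = np.hypot(a.data, b.data)
    denom = np.maximum(out_data, 1e-12)

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * a.data / denom)
        if b.requires_grad:
            b._accumulate(g * b.data / denom)

    return Tensor._make(out_data, (a, b), bw)


_REFLECT_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _reflect_index(H: int, W: int, ph: int, pw: int) -> np.ndarray:
    """Flat source index of each padded pixel, for scatter-add backward."""
    key = (H, W, ph, pw)
    if key not in _REFLECT_IDX_CACHE:
        idx = np.arange(H * W, dtype=np.int64).reshape(H, W)
        _REFLECT_IDX_CACHE[key] = np.pad(idx, ((ph, ph), (pw, pw)), mode="reflect").ravel()
    return _REFLECT_IDX_CACHE[key]


def pad_reflect(x: Tensor, ph: int, pw: int) -> Tensor:
    """Reflect-pad the spatial axes of an NHWC tensor."""
    pads = ((0, 0), (ph, ph), (pw, pw), (0, 0))
    out = np.pad(x.data, pads, mode="reflect")
    N, H, W, C = x.shape
    src = _reflect_index(H, W, ph, pw)

    def bw(g):
        g2 = g.reshape(N, -1, C)
        core = np.zeros((N, H * W, C), dtype=_F32)
        np.add.at(core, (slice(None), src), g2)
        x._accumulate(core.reshape(N, H, W, C))

    return Tensor._make(out, (x,), bw)


def pad_zero(x: Tensor, ph: int, pw: int) -> Tensor:
    pads = ((0, 0), (ph, ph), (pw, pw), (0, 0))
    N, H, W, C = x.shape

    def bw(g):
        x._accumulate(g[:, ph : ph + H, pw : pw + W, :])

    return Tensor._make(np.pad(x.data, pads), (x,), bw)


def roll(x: Tensor, shifts: tuple[int, int], axes: tuple[int, int] = (1, 2)) -> Tensor:
    def bw(g):
        x._accumulate(np.roll(g, tuple(-s for s in shifts), axis=axes))

    return Tensor._make(np.roll(x.data, shifts, axis=axes), (x,), bw)


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """table[idx] for an integer index array; gradients scatter-add."""

    def bw(g):
        full = np.zeros(table.shape, dtype=_F32)
        np.add.at(full, idx, g)
        table._accumulate(full)

    return Tensor._make(table.data[idx], (table,), bw)


# -- fixed linear resampling -------------------------------------------------

def _interp_matrix(n_out: int, n_in: int, mode: str) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix."""
    A = np.zeros((n_out, n_in), dtype=_F32)
    scale = n_in / n_out
    for i in range(n_out):
        if mode == "nearest":
            j = min(int((i + 0.5) * scale), n_in - 1)
            A[i, j] = 1.0
        else:  # bilinear, half-pixel centers
            src = (i + 0.5) * scale - 0.5
            j0 = int(np.floor(src))
            f = src - j0
            j0c = min(max(j0, 0), n_in - 1)
            j1c = min(max(j0 + 1, 0), n_in - 1)
            A[i, j0c] += 1.0 - f
            A[i, j1c] += f
    return A


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _cached_interp(n_out: int, n_in: int, mode: str) -> np.ndarray:
    key = (n_out, n_in, mode)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in, mode)
    return _INTERP_CACHE[key]


def upsample2d(x: Tensor, factor: int, mode: str = "bilinear") -> Tensor:
    """Resample an NHWC tensor by an integer factor with a fixed linear map."""
    N, H, W, C = x.shape
    Ah = _cached_interp(H * factor, H, mode)
    Aw = _cached_interp(W * factor, W, mode)

    def apply(arr, Mh, Mw):
        y = np.tensordot(Mh, arr, axes=([1], [1]))  # (Hout, N, W, C)
        y = np.moveaxis(y, 0, 1)
        y = np.tensordot(Mw, y, axes=([1], [2]))  # (Wout, N, Hout, C)
        return np.moveaxis(y, 0, 2).astype(_F32)

    def bw(g):
        x._accumulate(apply(g, Ah.T, Aw.T))

    return Tensor._make(apply(x.data, Ah, Aw), (x,), bw)
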