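"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's attention operators, classifiers and Grad-CAM all run on this
engine.  It implements exactly the primitives the models need: broadcasting
arithmetic, matmul, elementwise nonlinearities, axis reductions, shape ops,
2-D (grouped) convolution and max pooling.  Gradients are accumulated by a
topological backward sweep, torch-style but deliberately tiny.

Arrays are kept in float32 unless the caller supplies float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "max_pool2d"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype in (np.float32, np.float64):
        return a
    return a.astype(np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bw
        return out

    # -------------------------------------------------------- nonlinearities
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accum(g * e) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data) if self.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s)) if self.requires_grad else None
        return out

    def clamp(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along a single axis; gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = Tensor(out_data, _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gx)

        out._backward = bw
        return out

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig)) if self.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv)) if self.requires_grad else None
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self._accum(gx)

        out._backward = bw
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) -> (N, C, kh, kw, Ho, Wo)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho*,Wo*,kh,kw
    win = win[:, :, ::sh, ::sw]
    return win.transpose(0, 1, 4, 5, 2, 3)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, grouped (depthwise when groups == C_in)."""
    N, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    G = groups
    if C % G or Cout % G or Cg != C // G:
        raise ValueError(f"incompatible group structure: C={C}, Cout={Cout}, groups={G}, w Cin={Cg}")
    sh = sw = int(stride)
    Ho = (H + 2 * padding - kh) // sh + 1
    Wo = (W + 2 * padding - kw) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("kernel larger than padded input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = _im2col(xp, kh, kw, sh, sw)                                   # N,C,kh,kw,Ho,Wo
    cols = cols.reshape(N, G, Cg * kh * kw, Ho * Wo)
    wm = w.data.reshape(G, Cout // G, Cg * kh * kw)
    y = np.einsum("gok,ngkl->ngol", wm, cols, optimize=True).reshape(N, Cout, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Cout, 1, 1)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, _prev=prev)

    def bw(g):
        gy = g.reshape(N, G, Cout // G, Ho * Wo)
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gy, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gc = np.einsum("gok,ngol->ngkl", wm, gy, optimize=True)
            gc = gc.reshape(N, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += gc[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    out._backward = bw
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    k, s = kernel, stride
    Ho = (H + 2 * padding - k) // s + 1
    Wo = (W + 2 * padding - k) // s + 1
    pad_val = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=pad_val) if padding else x.data
    win = _im2col(xp, k, k, s, s).reshape(N, C, k * k, Ho, Wo)
    idx = np.argmax(win, axis=2)
    y = np.take_along_axis(win, idx[:, :, None], axis=2)[:, :, 0]
    out = Tensor(y, _prev=(x,))

    def bw(g):
        if not self_requires:
            return
        gxp = np.zeros_like(xp)
        ki, kj = np.divmod(idx, k)                          # N,C,Ho,Wo window offsets
        n_i, c_i, ho_i, wo_i = np.indices(idx.shape)
        np.add.at(gxp, (n_i, c_i, ho_i * s + ki, wo_i * s + kj), g)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accum(gxp)

    self_requires = x.requires_grad
    out._backward = bw
    return out
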