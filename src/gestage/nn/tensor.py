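"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the dual-branch age-regression network needs are
implemented: elementwise arithmetic, matrix product, ReLU, absolute value,
channel-axis maximum, clipping, bilinear up-sampling, and reductions.
Everything runs in float32. Gradients flow through the attention path
(channel max -> clip/rescale -> Gaussian product -> image mask), which is
what makes the whole model trainable end to end.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "upsample_matrix", "bilinear_upsample",
           "default_dtype", "set_default_dtype", "dtype_context"]

_DEFAULT_DTYPE = np.float32


def default_dtype():
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    """Set the float width for newly created tensors/parameters (float32 by
    default; float64 is useful for finite-difference gradient checks)."""
    global _DEFAULT_DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be numpy float32 or float64")
    _DEFAULT_DTYPE = dtype


@contextlib.contextmanager
def dtype_context(dtype):
    previous = _DEFAULT_DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(previous)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big backbones
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        def bw(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))
        return Tensor._node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))
        return Tensor._node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))
        return Tensor._node(self.data / other.data, (self, other), bw)

    def __pow__(self, exponent: float):
        def bw(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)
        return Tensor._node(self.data ** exponent, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        def bw(g):
            return ((self, g @ other.data.T), (other, self.data.T @ g))
        return Tensor._node(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- nonlinearities and shaping ---------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: ((self, g * mask),))

    def abs(self) -> "Tensor":
        sign = np.sign(self.data).astype(self.data.dtype)
        return Tensor._node(np.abs(self.data), (self,), lambda g: ((self, g * sign),))

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor._node(self.data.reshape(*shape), (self,),
                            lambda g: ((self, g.reshape(old)),))

    def clip(self, lo, hi) -> "Tensor":
        """Clamp to [lo, hi]; lo/hi are constants (scalars or broadcastable
        arrays). Gradient is 1 strictly inside the interval, else 0."""
        lo = np.asarray(lo, dtype=self.data.dtype)
        hi = np.asarray(hi, dtype=self.data.dtype)
        out = np.clip(self.data, lo, hi)
        inside = ((self.data > lo) & (self.data < hi)).astype(self.data.dtype)
        return Tensor._node(out, (self,), lambda g: ((self, g * inside),))

    def max_over_axis(self, axis: int) -> "Tensor":
        """Maximum along one axis (used for the channel-max heatmap);
        the gradient routes to the (first) argmax element."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                 axis=axis).squeeze(axis)
        def bw(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            return ((self, gx),)
        return Tensor._node(out, (self,), bw)

    def sum(self) -> "Tensor":
        shape = self.data.shape
        return Tensor._node(self.data.sum(), (self,),
                            lambda g: ((self, np.broadcast_to(g, shape).copy()),))

    def mean(self) -> "Tensor":
        n = self.data.size
        shape = self.data.shape
        return Tensor._node(self.data.mean(), (self,),
                            lambda g: ((self, np.broadcast_to(g / n, shape).copy()),))

    def mean_over(self, axes: tuple[int, ...]) -> "Tensor":
        n = int(np.prod([self.data.shape[a] for a in axes]))
        out = self.data.mean(axis=axes)
        def bw(g):
            ge = np.expand_dims(g, axes)
            return ((self, np.broadcast_to(ge / n, self.data.shape).copy()),)
        return Tensor._node(out, (self,), bw)

    def max_over_spatial(self) -> "Tensor":
        """Global max pool for (N, C, H, W) -> (N, C)."""
        n_, c, h, w = self.data.shape
        flat = self.data.reshape(n_, c, h * w)
        idx = np.argmax(flat, axis=2)
        out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        def bw(g):
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, idx[:, :, None], g[:, :, None], axis=2)
            return ((self, gx.reshape(self.data.shape)),)
        return Tensor._node(out, (self,), bw)

    def upsample_bilinear(self, size: tuple[int, int]) -> "Tensor":
        """Bilinear up-sampling of the trailing two axes (half-pixel centers,
        matching the common convention where corner alignment is disabled)."""
        h, w = self.data.shape[-2:]
        hh, ww = size
        wr = upsample_matrix(h, hh)
        wc = upsample_matrix(w, ww)
        out = np.einsum("ih,...hw,jw->...ij", wr, self.data, wc, optimize=True)
        def bw(g):
            return ((self, np.einsum("ih,...ij,jw->...hw", wr, g, wc,
                                     optimize=True)),)
        return Tensor._node(out, (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def upsample_matrix(src: int, dst: int) -> np.ndarray:
    """(dst, src) row-stochastic interpolation matrix for 1-D bilinear
    resampling with half-pixel sample centers."""
    if dst < src:
        raise ValueError(f"target size {dst} smaller than source {src}")
    m = np.zeros((dst, src), dtype=_DEFAULT_DTYPE)
    scale = src / dst
    coords = (np.arange(dst) + 0.5) * scale - 0.5
    coords = np.clip(coords, 0.0, src - 1.0)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = (coords - lo).astype(m.dtype)
    m[np.arange(dst), lo] += 1.0 - frac
    m[np.arange(dst), hi] += frac
    return m


def bilinear_upsample(array: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Plain-NumPy bilinear up-sample of the trailing two axes."""
    wr = upsample_matrix(array.shape[-2], size[0])
    wc = upsample_matrix(array.shape[-1], size[1])
    return np.einsum("ih,...hw,jw->...ij", wr,
                     np.asarray(array, dtype=_DEFAULT_DTYPE), wc, optimize=True)
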