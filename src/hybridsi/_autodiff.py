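"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The encoding and autoencoder networks in this package are a single
convolutional layer plus fully connected maps, so a small tape-based
engine is sufficient: every operation records its parents and a closure
that accumulates gradients into them.  Convolutions are expressed with
integer-array gathers (im2col) followed by BLAS matrix products, which
keeps both the forward and the backward pass inside optimized NumPy
kernels.

The engine is dtype-agnostic: computations follow the dtype of their
inputs (float32 for training, float64 where exactness matters in tests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self._grad_owned = False
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _add_grad(self, g: np.ndarray) -> None:
        # copy-on-write accumulation: the first contribution is aliased,
        # a second one triggers an owned buffer
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._add_grad(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._add_grad(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._add_grad(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._add_grad(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._add_grad(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._add_grad(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data**p, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._add_grad(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._add_grad(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g * val)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g / self.data)

        out._backward = backward
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g * (1.0 - val**2))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g * mask)

        out._backward = backward
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g * sign)

        out._backward = backward
        return out

    # -- reductions and shape ops --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._add_grad(np.broadcast_to(g, self.data.shape).astype(self.data.dtype, copy=False))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._add_grad(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                    self._grad_owned = True
                elif not self._grad_owned:
                    self.grad = self.grad.copy()
                    self._grad_owned = True
                np.add.at(self.grad, idx, g)

        out._backward = backward
        return out

    def flip(self, axis):
        out = Tensor(np.flip(self.data, axis=axis), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._add_grad(np.flip(g, axis=axis))

        out._backward = backward
        return out

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by `pad` on every side."""
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, width), _parents=(self,))
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def backward(g):
            if self.requires_grad:
                self._add_grad(g[sl])

        out._backward = backward
        return out

    # ------------------------------------------------------------------
    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None):
        """Reverse-mode sweep from this (typically scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order (graphs can be deep)
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_owned = True
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False


def concatenate(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._add_grad(g[tuple(sl)])

    out._backward = backward
    return out
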