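"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small volumetric CNNs on CPU; this module provides the
tensor graph those networks are built from.  Design constraints:

* correctness over generality — only the ops the model needs exist;
* gradients accumulate on every node (Grad-CAM reads gradients of
  intermediate activations, so nothing is freed eagerly);
* float32 by default for speed, float64 supported for finite-difference
  gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


class Tensor:
    """A numpy array plus a backward closure in a dynamically built DAG."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
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
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.ascontiguousarray(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this node through the whole graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by iterative DFS (graphs can be deep)
        order, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    # -------------------------------------------------------------- basic ops
    def __add__(self, other):
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=self.data.dtype))
        data = self.data + other.data
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), bwd, rg)

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            other = Tensor(np.asarray(other, dtype=self.data.dtype))
        data = self.data * other.data
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), bwd, rg)

    __radd__ = __add__
    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (other * -1.0 if isinstance(other, Tensor) else -np.asarray(other))

    def __neg__(self):
        return self * -1.0

    def reshape(self, *shape):
        orig = self.data.shape
        data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(data, (self,), bwd, self.requires_grad)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        data = np.ascontiguousarray(self.data.transpose(axes))

        def bwd(g):
            self._accum(g.transpose(tuple(inv)))

        return Tensor._make(data, (self,), bwd, self.requires_grad)

    def matmul(self, other: "Tensor"):
        """Batched matmul with numpy broadcasting over leading axes."""
        data = self.data @ other.data
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), bwd, rg)

    __matmul__ = matmul

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(data, (self,), bwd, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __pow__(self, p: float):
        data = self.data ** p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(data, (self,), bwd, self.requires_grad)

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(data, (self,), bwd, self.requires_grad)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bwd, self.requires_grad)


def _unbroadcast(g, shape):
    """Reduce gradient g (broadcast shape) back to the parent's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors, axis: int) -> Tensor:
    """Concatenate along an axis; the gradient is split back by slicing."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(data, tuple(tensors), bwd, rg)
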