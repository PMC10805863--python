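"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
ndarray and remembers the operation that produced it.  ``backward`` runs a
topological sort and accumulates gradients.  Only the operations needed by
the EEG and visual networks are provided (dense algebra, 2-D/1-D
convolution, pooling, elementwise nonlinearities, reductions, indexing).

Gradient correctness for every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _astensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = _astensor(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _astensor(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_astensor(other))

    def __rsub__(self, other):
        return _astensor(other) + (-self)

    def __truediv__(self, other):
        other = _astensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _astensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor._from_op(self.data ** p, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    # -- matmul ----------------------------------------------------------
    def __matmul__(self, other):
        other = _astensor(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if b.ndim > 1 else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor._from_op(self.data * mask, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._from_op(s, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor._from_op(t, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor._from_op(e, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = bw
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor._from_op(np.abs(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        val = m + np.log(s)
        softmax = e / s
        if not keepdims:
            val = np.squeeze(val, axis=axis)
        out = Tensor._from_op(val, (self,), None)

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * softmax)

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor._from_op(self.data.reshape(shape), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor._from_op(self.data.transpose(axes), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor._from_op(self.data[idx], (self,), None)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        out = Tensor._from_op(np.pad(self.data, pad_width), (self,), None)
        slices = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, self.data.shape))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g[slices])

        out._backward = bw
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [_astensor(t) for t in tensors]
    out = Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [_astensor(t) for t in tensors]
    out = Tensor._from_op(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), None)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bw
    return out
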