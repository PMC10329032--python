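"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based autodiff core sized for the small attention and
convolution models in this package (tens to hundreds of thousands of
parameters).  Every differentiable operation builds a node holding its
parents and a closure that accumulates gradients into them;
:meth:`Tensor.backward` runs the tape in reverse topological order.

All arithmetic uses the module-level ``DTYPE`` (float64 by default,
switchable to float32 for speed).  Broadcasting follows numpy semantics;
the gradient of a broadcast operand is summed back to its original shape.
"""

from __future__ import annotations

from contextlib import contextmanager as _contextmanager

import numpy as np
from scipy import special as _special

#: float dtype for all tensor arithmetic; float32 roughly halves training
#: time at a precision amply sufficient for SGD, float64 is the default
DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the global tensor dtype (numpy float32 or float64)."""
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be numpy float32 or float64")
    DTYPE = dtype


@_contextmanager
def using_dtype(dtype):
    """Scoped tensor-dtype switch (e.g. float32 for long training runs)."""
    global DTYPE
    previous = DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        DTYPE = previous


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.data, self.data.shape))
            if other.requires_grad:
                g = -grad * self.data / (other.data ** 2)
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * p * self.data ** (p - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = np.matmul(a, b)

        def backward(grad):
            if self.requires_grad:
                if b.ndim == 2:
                    # batched input x 2-D matrix: one flattened GEMM
                    g = (grad.reshape(-1, grad.shape[-1]) @ b.T).reshape(
                        self.data.shape)
                else:
                    g = _unbroadcast(np.matmul(grad, np.swapaxes(b, -1, -2)),
                                     self.data.shape)
                self._accumulate(g)
            if other.requires_grad:
                if b.ndim == 2 and a.ndim > 2:
                    g = a.reshape(-1, a.shape[-1]).T @ grad.reshape(
                        -1, grad.shape[-1])
                else:
                    g = _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), grad),
                                     b.shape)
                other._accumulate(g)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            ref = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                ref = np.expand_dims(ref, axis)
            mask = (self.data == ref)
            # split gradient evenly among ties
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None \
                else mask.sum()
            self._accumulate(mask * g / counts)

        return Tensor._from_op(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad / self.data)

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def erf(self):
        out_data = _special.erf(self.data)

        def backward(grad):
            if self.requires_grad:
                d = 2.0 / np.sqrt(np.pi) * np.exp(-self.data ** 2)
                self._accumulate(grad * d)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.data.shape

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(in_shape))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inverse = tuple(np.argsort(axes))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.transpose(inverse))

        return Tensor._from_op(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        in_shape = self.data.shape

        def backward(grad):
            if self.requires_grad:
                full = np.zeros(in_shape)
                np.add.at(full, idx, grad)
                self._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)
        in_shape = self.data.shape

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, in_shape))

        return Tensor._from_op(out_data, (self,), backward)

    # -- tape -----------------------------------------------------------------

    def _accumulate(self, grad: np.ndarray):
        # gradients are never mutated in place, so views may be stored as-is
        if self.grad is None:
            if not (isinstance(grad, np.ndarray) and grad.dtype == self.data.dtype):
                grad = np.asarray(grad, dtype=self.data.dtype)
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None):
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor without grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


class Parameter(Tensor):
    """A leaf tensor registered as trainable by :class:`hdsemg.nn.modules.Module`."""

    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)
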