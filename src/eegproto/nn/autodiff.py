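"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything the two network architectures need — broadcasting arithmetic,
matmul, the usual nonlinearities, reductions, and a handful of custom ops
defined in :mod:`eegproto.nn.layers` — is expressed as :class:`Tensor`
operations that record a backward closure. ``Tensor.backward()`` runs the
tape in reverse topological order. CPU-only and fully deterministic.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    previous = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    #: make numpy defer to the reflected operators instead of broadcasting
    #: elementwise over a Tensor operand
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ---------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the closure reference cycles so the graph is freed by
        # refcounting instead of waiting for a gc pass
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, self, other)

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        if out.requires_grad:
            out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, self, other)

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        if out.requires_grad:
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _node(self.data ** exponent, self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

        if out.requires_grad:
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, self, other)

        def backward():
            if self.requires_grad:
                grad = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                grad = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accumulate(_unbroadcast(grad, other.shape))

        if out.requires_grad:
            out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out = _node(np.exp(self.data), self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        if out.requires_grad:
            out._backward = backward
        return out

    def log(self):
        out = _node(np.log(self.data), self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        if out.requires_grad:
            out._backward = backward
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        if out.requires_grad:
            out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        if out.requires_grad:
            out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _node(t, self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - t * t))

        if out.requires_grad:
            out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only inside the open interval."""
        out = _node(np.clip(self.data, lo, hi), self)

        def backward():
            if self.requires_grad:
                mask = (self.data > lo) & (self.data < hi)
                self._accumulate(out.grad * mask)

        if out.requires_grad:
            out._backward = backward
        return out

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), self)

        def backward():
            if self.requires_grad:
                grad = out.grad
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accumulate(np.broadcast_to(grad, self.shape).copy())

        if out.requires_grad:
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), self)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        if out.requires_grad:
            out._backward = backward
        return out

    def softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _node(s, self)

        def backward():
            if self.requires_grad:
                dot = (out.grad * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (out.grad - dot))

        if out.requires_grad:
            out._backward = backward
        return out


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
        out.requires_grad = any(p.requires_grad for p in parents)
    return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), *tensors)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    if out.requires_grad:
        out._backward = backward
    return out


def custom_op(data: np.ndarray, parents: tuple[Tensor, ...], backward_fn) -> Tensor:
    """Build a graph node whose backward is supplied by the caller.

    ``backward_fn(out_grad)`` must call ``parent._accumulate`` itself for
    every parent that requires a gradient.
    """
    out = _node(data, *parents)

    def backward():
        backward_fn(out.grad)

    if out.requires_grad:
        out._backward = backward
    return out
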