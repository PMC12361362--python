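"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numeric core behind the trainable models in :mod:`cardiokit.adsvm`
and :mod:`cardiokit.amccnet`.  It implements exactly the operations those
models need — broadcast arithmetic, (batched) matrix products, the activation
functions of the tuning table, axis reductions and shape surgery — with dense
float64 arrays and a topologically ordered backward sweep.  Everything is
deterministic: the same parameter values and inputs always produce the same
gradients, which is what makes seeded training runs reproducible down to the
last bit.

Only what the package needs is implemented; this is not a general tensor
library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "sigmoid", "softplus"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _sum_to_shape(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data + other.data, (self, other), None)

        def backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._node(-self.data, (self,), None)
        out._backward = (lambda: self._accum(-out.grad)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data * other.data, (self, other), None)

        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data / other.data, (self, other), None)

        def backward():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data**2)

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._node(self.data**exponent, (self,), None)

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data @ other.data, (self, other), None)

        def backward():
            self._accum(out.grad @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ out.grad)

        out._backward = backward if out.requires_grad else None
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        value = np.exp(self.data)
        out = Tensor._node(value, (self,), None)
        out._backward = (lambda: self._accum(out.grad * value)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor._node(np.log(self.data), (self,), None)
        out._backward = (lambda: self._accum(out.grad / self.data)) if out.requires_grad else None
        return out

    def sqrt(self):
        value = np.sqrt(self.data)
        out = Tensor._node(value, (self,), None)
        out._backward = (
            (lambda: self._accum(out.grad * 0.5 / value)) if out.requires_grad else None
        )
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor._node(value, (self,), None)
        out._backward = (
            (lambda: self._accum(out.grad * (1.0 - value**2))) if out.requires_grad else None
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._node(self.data * mask, (self,), None)
        out._backward = (lambda: self._accum(out.grad * mask)) if out.requires_grad else None
        return out

    def leaky_relu(self, alpha: float = 0.01):
        slope = np.where(self.data > 0, 1.0, alpha)
        out = Tensor._node(self.data * slope, (self,), None)
        out._backward = (lambda: self._accum(out.grad * slope)) if out.requires_grad else None
        return out

    def elu(self, alpha: float = 1.0):
        value = np.where(self.data > 0, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        slope = np.where(self.data > 0, 1.0, value + alpha)
        out = Tensor._node(value, (self,), None)
        out._backward = (lambda: self._accum(out.grad * slope)) if out.requires_grad else None
        return out

    # -- reductions and shape surgery --------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward():
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accum(np.broadcast_to(grad, self.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor._node(self.data.reshape(*shape), (self,), None)
        out._backward = (
            (lambda: self._accum(out.grad.reshape(self.data.shape)))
            if out.requires_grad
            else None
        )
        return out

    def transpose(self, axes):
        inverse = np.argsort(axes)
        out = Tensor._node(self.data.transpose(axes), (self,), None)
        out._backward = (
            (lambda: self._accum(out.grad.transpose(inverse))) if out.requires_grad else None
        )
        return out

    def __getitem__(self, key):
        out = Tensor._node(self.data[key], (self,), None)

        def backward():
            grad = np.zeros_like(self.data)
            grad[key] = out.grad
            self._accum(grad)

        out._backward = backward if out.requires_grad else None
        return out

    def pad_last(self, left: int, right: int):
        """Zero-pad the final axis (used for "same" convolutions)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(left, right)]
        out = Tensor._node(np.pad(self.data, width), (self,), None)
        stop = -right if right else None

        def backward():
            self._accum(out.grad[..., left:stop])

        out._backward = backward if out.requires_grad else None
        return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for tensor, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * out.data.ndim
            index[axis] = slice(start, stop)
            tensor._accum(out.grad[tuple(index)])

    out._backward = backward if out.requires_grad else None
    return out


def sigmoid(x: Tensor) -> Tensor:
    value = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic
    out = Tensor._node(value, (x,), None)
    out._backward = (
        (lambda: x._accum(out.grad * value * (1.0 - value))) if out.requires_grad else None
    )
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) with the standard overflow-safe forward/backward."""
    value = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    grad_local = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    out = Tensor._node(value, (x,), None)
    out._backward = (lambda: x._accum(out.grad * grad_local)) if out.requires_grad else None
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g**2
            m_hat = self._m[i] / (1 - self.beta1**self._t)
            v_hat = self._v[i] / (1 - self.beta2**self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
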