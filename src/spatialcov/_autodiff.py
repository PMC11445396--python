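"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for dense feed-forward networks with count
likelihoods: broadcast arithmetic, matmul, slicing/concat, reductions, the
standard nonlinearities, and ``gammaln`` (whose gradient is the digamma
function) for negative-binomial terms.  Gradient correctness is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln as _gammaln

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # sum away leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        # supports 2D and equal-rank batched stacks; no batch broadcasting
        other = self._lift(other)

        def backward(g, out):
            return (
                g @ np.swapaxes(other.data, -1, -2),
                np.swapaxes(self.data, -1, -2) @ g,
            )

        return self._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, out):
            return (g * p * self.data ** (p - 1),)

        return self._make(self.data**p, (self,), backward)

    # -- shape ops -------------------------------------------------------
    def __getitem__(self, key):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._make(self.data[key], (self,), backward)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g, out):
            return (g.reshape(orig),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g, out):
            return (g.T,)

        return self._make(self.data.T, (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if axis is None:
                return (np.full(self.shape, g),)
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g, out: (g * out.data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g, out: (g / (2 * out.data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g, out: (g * (1 - out.data**2),))

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        return self._make(out_data, (self,), lambda g, out: (g * (self.data > 0),))

    def sigmoid(self):
        out_data = 0.5 * (1 + np.tanh(0.5 * self.data))  # stable logistic

        def backward(g, out):
            return (g * out.data * (1 - out.data),)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, out):
            return (g * 0.5 * (1 + np.tanh(0.5 * self.data)),)

        return self._make(out_data, (self,), backward)

    def gammaln(self):
        def backward(g, out):
            return (g * digamma(self.data),)

        return self._make(_gammaln(self.data), (self,), backward)

    # -- autodiff driver --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS to avoid recursion limits
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, _):
            return tuple(np.split(g, splits, axis=axis))

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam optimiser with optional piecewise-constant learning rate and
    global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad**2).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
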