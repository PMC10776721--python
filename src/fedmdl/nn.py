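"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

This is the numerical substrate for every trainable component in the
package: the ClusterGAN generator/discriminator/encoder, the per-domain
classifier heads, and the graph attention network. It implements exactly
the operations those models need — dense layers, the usual activations,
broadcast-aware arithmetic, reductions, a fused softmax cross-entropy —
with gradients checked against finite differences in the test suite.

Arrays are float64 throughout: the models here are desk-scale, so we buy
gradient-check headroom instead of speed.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "Dense",
    "MLP",
    "SGD",
    "xavier_init",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
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

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = _backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _backward
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = _backward
        return out

    def rows(self, index) -> "Tensor":
        """Select rows by an integer index array (gather with accumulation)."""
        index = np.asarray(index)
        out = Tensor(self.data[index], self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accum(g)

        out._backward = _backward
        return out

    def cols(self, lo: int, hi: int) -> "Tensor":
        """Select a contiguous column slice [lo, hi) of a 2-D tensor."""
        out = Tensor(self.data[:, lo:hi], self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, lo:hi] = out.grad
                self._accum(g)

        out._backward = _backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data ** 2))

        out._backward = _backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = _backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = _backward
        return out

    def elu(self, alpha: float = 1.0):
        out = Tensor(np.where(self.data > 0, self.data, alpha * (np.exp(self.data) - 1.0)),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0,
                                                out.data + alpha))

        out._backward = _backward
        return out

    # ----------------------------------------------------------------- fused
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                dot = (out.grad * s).sum(axis=axis, keepdims=True)
                self._accum(s * (out.grad - dot))

        out._backward = _backward
        return out

    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy of row logits against integer labels."""
        labels = np.asarray(labels, dtype=np.intp)
        n = self.data.shape[0]
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=1))
        losses = logsumexp - shifted[np.arange(n), labels]
        out = Tensor(losses.mean(), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                p = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
                p[np.arange(n), labels] -= 1.0
                self._accum(out.grad * p / n)

        out._backward = _backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = _backward
    return out


# ---------------------------------------------------------------------- layers

def xavier_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Xavier/Glorot uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "linear": lambda t: t,
    "tanh": Tensor.tanh,
    "relu": Tensor.relu,
    "sigmoid": Tensor.sigmoid,
    "elu": Tensor.elu,
    "leaky_relu": Tensor.leaky_relu,
}


class Module:
    """Base class: a named, ordered bag of parameter tensors."""

    def parameters(self) -> "OrderedDict[str, Tensor]":
        raise NotImplementedError

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def get_state(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy()) for k, v in self.parameters().items())

    def set_state(self, state: "OrderedDict[str, np.ndarray]"):
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("state names do not match module parameters")
        for k, v in params.items():
            v.data = np.array(state[k], dtype=np.float64).reshape(v.data.shape)


class Dense(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, name: str = "dense"):
        self.name = name
        self.W = Tensor(xavier_init(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return OrderedDict([(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)])


class MLP(Module):
    """Dense stack with per-layer activations given by name."""

    def __init__(self, rng: np.random.Generator, sizes: Sequence[int],
                 activations: Sequence[str], name: str = "mlp"):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        self.name = name
        self.activations = list(activations)
        self.layers = [Dense(rng, a, b, name=f"{name}.{i}")
                       for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]))]

    def __call__(self, x: Tensor) -> Tensor:
        for layer, act in zip(self.layers, self.activations):
            x = _ACTIVATIONS[act](layer(x))
        return x

    def parameters(self):
        out: "OrderedDict[str, Tensor]" = OrderedDict()
        for layer in self.layers:
            out.update(layer.parameters())
        return out


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params: "OrderedDict[str, Tensor]", lr: float,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        if lr < 0:
            raise ValueError("lr must be nonnegative")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v = self._velocity[k]
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
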