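"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph auto-encoder and the
fully-connected head need: broadcasting arithmetic, matrix products,
row gather/scatter (for edge-list message passing), stable sigmoid /
softplus / log-sigmoid, ReLU, reductions, and a row-wise Euclidean norm.
Everything is float64 and single-threaded-deterministic.

Not a general tensor library: no views, no in-place ops, no higher-order
gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float64)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
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
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, (self, other))

        def bw(g):
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            elif a.ndim == 2 and b.ndim == 1:   # (n,k)@(k,) -> (n,)
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 2:   # (k,)@(k,m) -> (m,)
                self._accum(b @ g)
                other._accum(np.outer(a, g))
            else:                               # (k,)@(k,) -> scalar
                self._accum(g * b)
                other._accum(g * a)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def take_rows(self, idx: np.ndarray):
        """Gather rows (or elements of a 1-D tensor) by integer index."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out

    def segment_sum(self, seg_ids: np.ndarray, num_segments: int):
        """Sum rows (or scalars) into ``num_segments`` bins given by seg_ids."""
        seg_ids = np.asarray(seg_ids)
        shape = (num_segments,) + self.data.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, seg_ids, self.data)
        out = Tensor(acc, (self,))
        out._backward = lambda g: self._accum(g[seg_ids])
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bw(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = bw
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def row_norms_sum(self, eps: float = 1e-12):
        """``sum_i ||row_i||_2`` with a guarded gradient at zero rows."""
        norms = np.sqrt((self.data**2).sum(axis=1))
        out = Tensor(norms.sum(), (self,))

        def bw(g):
            self._accum(g * self.data / np.maximum(norms, eps)[:, None])

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def softplus(self):
        """log(1 + exp(x)), overflow-safe."""
        x = self.data
        sp = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(sp, (self,))
        sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out._backward = lambda g: self._accum(g * sig)
        return out

    def logsigmoid(self):
        """log(sigmoid(x)) = -softplus(-x), overflow-safe."""
        return -((-self).softplus())


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    """Glorot/Xavier uniform initialisation U(-limit, limit)."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimiser with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
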