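"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the NER stack needs: broadcasting
arithmetic, (batched) matmul, elementwise nonlinearities, reductions, a
numerically stable ``logsumexp``, row gathering for embedding lookup, and
shape manipulation.  All tensors are float64; graphs are rebuilt per
training step, so no retain/free bookkeeping is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "logsumexp", "take_rows", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        arr = np.asarray(data)
        if arr.dtype != np.float64:
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._bw = bw

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None:
                node._bw(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(self.data ** exponent, (self,), bw)

    def __matmul__(self, other):
        assert isinstance(other, Tensor)

        def bw(g):
            self._accum(
                _unbroadcast(np.matmul(g, other.data.swapaxes(-1, -2)), self.data.shape)
            )
            other._accum(
                _unbroadcast(np.matmul(self.data.swapaxes(-1, -2), g), other.data.shape)
            )

        return Tensor(np.matmul(self.data, other.data), (self, other), bw)

    # -- elementwise ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, (self,), bw)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), (self,), bw)


def tensor(data) -> Tensor:
    return Tensor(data)


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp; gradient is the softmax along `axis`."""
    m = np.max(t.data, axis=axis, keepdims=True)
    shifted = np.exp(t.data - m)
    total = shifted.sum(axis=axis, keepdims=True)
    out_data = (np.log(total) + m)
    soft = shifted / total

    def bw(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        t._accum(gg * soft)

    return Tensor(out_data if keepdims else np.squeeze(out_data, axis=axis), (t,), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    return (t - logsumexp(t, axis=axis, keepdims=True)).exp()


def take_rows(t: Tensor, idx) -> Tensor:
    """Gather rows (embedding lookup); backward scatter-adds."""
    idx = np.asarray(idx)

    def bw(g):
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        np.add.at(t.grad, idx, g)

    return Tensor(t.data[idx], (t,), bw)


class AdamW:
    """Adam with decoupled weight decay over a name->Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
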