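"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the models in this package need: broadcasted
arithmetic, batched matrix products on the trailing axes, reductions,
elementwise nonlinearities, concatenation, slicing and reshaping.  Gradients
are dense float64 arrays; graphs are built per call and freed afterwards.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp", "softplus"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of `self` (a scalar unless `grad` given)."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in node._backward(node.grad):
                g = _unbroadcast(g, parent.data.shape)
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = _as_tensor(other)
        return self._make(self.data + o.data, (self, o),
                          lambda g: ((self, g), (o, g)))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        o = _as_tensor(other)
        return self._make(self.data - o.data, (self, o),
                          lambda g: ((self, g), (o, -g)))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        o = _as_tensor(other)
        return self._make(self.data * o.data, (self, o),
                          lambda g: ((self, g * o.data), (o, g * self.data)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        return self._make(self.data / o.data, (self, o),
                          lambda g: ((self, g / o.data),
                                     (o, -g * self.data / o.data ** 2)))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, k: float):
        return self._make(self.data ** k, (self,),
                          lambda g: ((self, g * k * self.data ** (k - 1)),))

    def __matmul__(self, other):
        """Batched matmul on trailing two axes; `other` must be 2-D (weights)."""
        o = _as_tensor(other)
        out = self.data @ o.data

        def backward(g):
            gx = g @ o.data.T
            x2 = self.data.reshape(-1, self.data.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            gw = x2.T @ g2
            return ((self, gx), (o, gw))

        return self._make(out, (self, o), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: ((self, g.reshape(old)),))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return self._make(self.data[idx], (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.data.shape)),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(gg, self.data.shape)),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- element-wise
    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: ((self, g * out),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))

    def tanh(self):
        out = np.tanh(self.data)
        return self._make(out, (self,), lambda g: ((self, g * (1 - out ** 2)),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return self._make(out, (self,), lambda g: ((self, g * out * (1 - out)),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), numerically stable for large |x|."""
    out = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return x._make(out, (x,), lambda g: ((x, g * sig),))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    out = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    soft = np.exp(x.data - out)  # softmax weights
    res = out if keepdims else np.squeeze(out, axis=axis)

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return ((x, gg * soft),)

    return x._make(res, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    out = Tensor(data)
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
    return out
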