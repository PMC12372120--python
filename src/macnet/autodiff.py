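"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train the small feed-forward + self-attention
networks in this package: broadcast-aware elementwise arithmetic, (batched)
matrix products, ReLU, softmax/log-softmax with analytic backward passes,
shape manipulation and reductions. Gradients are accumulated by a topological
sweep over the recorded graph. Everything is float64; there is no graph
reuse — each forward pass builds a fresh graph, as the training loops here
always do.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gradcheck"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS post-order
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                )

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        return self._make(y, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        y = np.exp(out)

        def backward(g):
            if self.requires_grad:
                self._accum(g - y * g.sum(axis=axis, keepdims=True))

        return self._make(out, (self,), backward)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    # -- reductions / indexing ----------------------------------------------

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.shape).copy())

        return self._make(self.data.mean(), (self,), backward)

    def take_rows(self, col_index: np.ndarray):
        """Pick ``out[i] = self[i, col_index[i]]`` (per-row gather)."""
        col_index = np.asarray(col_index, dtype=np.int64)
        rows = np.arange(self.shape[0])

        def backward(g):
            if self.requires_grad:
                full = np.zeros(self.shape)
                np.add.at(full, (rows, col_index), g)
                self._accum(full)

        return self._make(self.data[rows, col_index], (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def gradcheck(fn, tensors: list[Tensor], eps: float = 1e-6) -> float:
    """Max abs difference between analytic and central-difference gradients."""
    for t in tensors:
        t.zero_grad()
    out = fn()
    out.backward()
    worst = 0.0
    for t in tensors:
        flat = t.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn().data.item()
            flat[i] = orig - eps
            lo = fn().data.item()
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            worst = max(worst, abs(num - t.grad.ravel()[i]))
    return worst
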