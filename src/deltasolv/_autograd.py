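"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph networks need: dense affine
maps, elementwise nonlinearities, gather/segment reductions for batched
graphs, and concatenation.  Gradients are accumulated with a topological
backward pass.  No GPU, no broadcasting beyond what the ops declare.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_max",
    "segment_softmax",
    "batched_matvec",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=np.float64), requires_grad=True)

    @staticmethod
    def const(data) -> "Tensor":
        return Tensor(data, requires_grad=False)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------------
    def _binary(self, other, fwd, bwd):
        other = other if isinstance(other, Tensor) else Tensor.const(other)
        out_data = fwd(self.data, other.data)

        def backward(grad, out):
            ga, gb = bwd(grad, self.data, other.data, out)
            if self.requires_grad:
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b, o: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b, o: (g, -g))

    def __rsub__(self, other):
        return Tensor.const(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b, o: (g * b, g * a))

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor.const(other)
        out_data = self.data @ other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return Tensor(out_data, parents=(self, other), backward=backward)

    # -- elementwise ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0.0

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * (1.0 - out_data * out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def exp(self):
        out_data = np.exp(np.clip(self.data, -500, 500))

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def square(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * 2.0 * self.data)

        return Tensor(self.data * self.data, parents=(self,), backward=backward)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(grad, out):
            if self.requires_grad:
                g = np.asarray(grad)
                if axis is not None:
                    g = np.expand_dims(g, axis=axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        old_shape = self.data.shape

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.reshape(old_shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def slice_cols(self, start, stop):
        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, start:stop] = grad
                self._accum(g)

        return Tensor(self.data[:, start:stop], parents=(self,), backward=backward)

    # -- graph machinery -----------------------------------------------------
    def _accum(self, grad):
        # never mutate in place: stored grads may alias a producer's output
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    offsets = np.cumsum([0] + [d.shape[axis] for d in datas])

    def backward(grad, out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(grad[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Row gather: out[k] = x[index[k]]."""
    index = np.asarray(index, dtype=np.intp)

    def backward(grad, out):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, index, grad)
            x._accum(g)

    return Tensor(x.data[index], parents=(x,), backward=backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)

    def backward(grad, out):
        if x.requires_grad:
            x._accum(grad[segment_ids])

    return Tensor(out_data, parents=(x,), backward=backward)


def segment_max(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment max; gradient routes to the (first) argmax element."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(out_data, segment_ids, x.data)
    # winner mask: element equals its segment max (split ties evenly)
    winners = (x.data == out_data[segment_ids]).astype(np.float64)
    counts = np.zeros_like(out_data)
    np.add.at(counts, segment_ids, winners)
    counts[counts == 0.0] = 1.0

    def backward(grad, out):
        if x.requires_grad:
            x._accum(grad[segment_ids] * winners / counts[segment_ids])

    return Tensor(out_data, parents=(x,), backward=backward)


def batched_matvec(A: Tensor, x: Tensor) -> Tensor:
    """Per-row matrix-vector product: out[e] = x[e] @ A[e].

    A has shape (E, d, d); x has shape (E, d); the result is (E, d).
    """
    out_data = np.matmul(x.data[:, None, :], A.data)[:, 0, :]

    def backward(grad, out):
        if A.requires_grad:
            A._accum(x.data[:, :, None] * grad[:, None, :])
        if x.requires_grad:
            x._accum(np.matmul(A.data, grad[:, :, None])[:, :, 0])

    return Tensor(out_data, parents=(A, x), backward=backward)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax normalized within each segment. `scores` is 1-D (n,)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    # max-shift for stability; the shift is treated as a constant (its
    # gradient contribution cancels exactly for softmax)
    m = np.full(n_segments, -np.inf)
    np.maximum.at(m, segment_ids, scores.data)
    shifted = scores - Tensor.const(m[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e.reshape(-1, 1), segment_ids, n_segments)
    inv = Tensor(1.0 / denom.data, parents=(denom,), backward=lambda g, o: denom._accum(
        -g / (denom.data * denom.data)) if denom.requires_grad else None)
    return e * gather(inv, segment_ids).reshape(-1)
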