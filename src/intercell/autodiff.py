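"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the graph encoders, decoders and training
loop need: broadcast arithmetic, matrix products, relu / leaky-relu /
softplus, reductions, row gather/scatter, and a per-segment softmax used for
attention over incoming edges. Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "relu",
    "leaky_relu",
    "softplus",
    "tsum",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------
    def _make(self, data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=parents if req else (),
                      backward=backward if req else None)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def backward(self):
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad and g is not None:
                    parent.grad = g if parent.grad is None else parent.grad + g


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        return (g @ b.data.T, a.data.T @ g)

    return a._make(out, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return a._make(a.data * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0
    factor = np.where(mask, 1.0, slope)
    return a._make(a.data * factor, (a,), lambda g: (g * factor,))


def softplus(a: Tensor) -> Tensor:
    out = np.logaddexp(0.0, a.data)
    sig = 1.0 / (1.0 + np.exp(-a.data))
    return a._make(out, (a,), lambda g: (g * sig,))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return a._make(out, (a,), backward)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return a._make(out, (a,), backward)


def segment_sum(a: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `a` into `n_segments` buckets given by `seg`."""
    seg = np.asarray(seg, dtype=np.intp)
    out = np.zeros((n_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out, seg, a.data)

    def backward(g):
        return (g[seg],)

    return a._make(out, (a,), backward)


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment.

    Segments with no members simply contribute nothing; scores are shifted
    by the per-segment max for stability.
    """
    seg = np.asarray(seg, dtype=np.intp)
    s = scores.data
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, seg, s)
    ex = np.exp(s - seg_max[seg])
    denom = np.zeros(n_segments)
    np.add.at(denom, seg, ex)
    out = ex / denom[seg]

    def backward(g):
        # d softmax: out * (g - sum_within_segment(g * out))
        go = g * out
        seg_go = np.zeros(n_segments)
        np.add.at(seg_go, seg, go)
        return (go - out * seg_go[seg],)

    return scores._make(out, (scores,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
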