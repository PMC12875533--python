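"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the graph encoders, the dual-task
decoders and the masked expression networks: a :class:`Tensor` wrapping an
``ndarray`` with a gradient slot, a small set of vectorized operations
(including the gather / segment-sum pair needed for message passing and
per-target softmax), and an Adam optimizer.

Gradients flow through a dynamically built tape; ``Tensor.backward`` walks
it in reverse topological order. Broadcasting in forward ops is undone in
the backward pass by summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concat",
    "segment_softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * mask)

        out._backward = bwd
        return out

    def leaky_relu(self, alpha: float = 0.01):
        slope = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * slope, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * slope)

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(e, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * e)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g / self.data)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * mask)

        out._backward = bwd
        return out

    def square(self):
        return self * self

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structural ops ------------------------------------------------
    def take_rows(self, idx: np.ndarray):
        """Gather rows (axis 0); backward scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bwd
        return out

    def segment_sum(self, seg: np.ndarray, n_segments: int):
        """Sum rows sharing a segment id into ``n_segments`` rows."""
        seg = np.asarray(seg, dtype=np.intp)
        shape = (n_segments,) + self.data.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, seg, self.data)
        out = Tensor(acc, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g[seg])

        out._backward = bwd
        return out

    def transpose(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g.T)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- backward ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad or t._prev for t in tensors),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._prev:
                t._accum(piece)

    out._backward = bwd
    return out


def segment_softmax(logits: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax over groups of rows sharing a segment id.

    Used for per-target-node attention normalization: within each segment
    (target node) the returned values are positive and sum to 1. The
    per-segment max is treated as a constant shift (the standard
    numerically stable trick; it does not change the gradient).
    """
    seg = np.asarray(seg, dtype=np.intp)
    mx = np.full(n_segments, -np.inf)
    np.maximum.at(mx, seg, logits.data)
    mx[~np.isfinite(mx)] = 0.0
    shifted = logits - constant(mx[seg])
    e = shifted.exp()
    denom = e.segment_sum(seg, n_segments).take_rows(seg)
    return e / denom


def segment_max(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Elementwise max over rows sharing a segment id.

    Empty segments yield 0. The backward pass distributes the gradient
    over the attaining rows (split evenly on ties — a valid subgradient).
    """
    seg = np.asarray(seg, dtype=np.intp)
    shape = (n_segments,) + x.data.shape[1:]
    mx = np.full(shape, -np.inf)
    np.maximum.at(mx, seg, x.data)
    mx[~np.isfinite(mx)] = 0.0
    attain = (x.data == mx[seg]).astype(float)
    counts = np.zeros(shape)
    np.add.at(counts, seg, attain)
    out = Tensor(mx, x.requires_grad, (x,))

    def bwd(g):
        share = np.where(counts[seg] > 0, attain / np.maximum(counts[seg], 1),
                         0.0)
        x._accum(g[seg] * share)

    out._backward = bwd
    return out


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
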