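"""Compact reverse-mode automatic differentiation over numpy arrays.

The whole HTGRS model (reference encoder, R-GCN, relation-segmentation
stack, bilinear classifier, adaptive-threshold loss) is differentiable
end-to-end through this module.  Tensors wrap float64 numpy arrays and
record a tape of parent tensors plus a backward closure; :meth:`Tensor.backward`
walks the tape in reverse topological order.

Only the operations the model needs are implemented: broadcasted
arithmetic, (batched) matmul, reductions, the usual nonlinearities,
fused softmax / logsumexp, gather-style indexing, concatenation and a
5x5 same-padded 2-D convolution.  Everything is double precision so the
loop-based oracles in the test-suite can be matched to tight tolerances.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concatenate",
    "stack",
    "conv2d_same",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; graphs can be a few thousand nodes deep
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(data, (self, other), backward)

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        data = a @ b

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    ga = g * b
                elif b.ndim == 1:  # (..., n, m) @ (m,) -> (..., n)
                    ga = np.multiply.outer(g, b) if g.ndim == 0 else g[..., None] * b
                elif a.ndim == 1:  # (m,) @ (..., m, p) -> (..., p)
                    ga = (b @ g[..., None])[..., 0]
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(np.asarray(ga), self.shape))
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    gb = g * a
                elif a.ndim == 1:  # gb shape (..., m, p)
                    gb = np.multiply.outer(a, g) if g.ndim <= 1 else a[:, None] * g[..., None, :]
                elif b.ndim == 1:
                    gb = np.swapaxes(a, -1, -2) @ g[..., None] if g.ndim > 0 else a * g
                    gb = gb[..., 0] if gb.ndim > 1 else gb
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(np.asarray(gb), other.shape))

        return self._make(data, (self, other), backward)

    def __rmatmul__(self, other):
        return Tensor.as_tensor(other) @ self

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))
        data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return self._make(data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max-reduce along ``axis``; gradient flows to the first argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            idx = list(np.indices(arg.shape))
            idx.insert(axis if axis >= 0 else self.ndim + axis, arg)
            np.add.at(acc, tuple(idx), np.squeeze(gg, axis=axis))
            self._accum(acc)

        return self._make(data, (self,), backward)

    def logsumexp(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Numerically stable log-sum-exp (max-shift trick); fused gradient."""
        m = self.data.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out = np.log(s) + m
        soft = e / s

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(gg * soft)

        return self._make(out if keepdims else np.squeeze(out, axis=axis), (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        return self._make(y, (self,), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(data, (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data**2))

        return self._make(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return self._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return self._make(data, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def conv2d_same(x: Tensor, weight: Tensor, bias: Tensor, kernel: int = 5) -> Tensor:
    """2-D convolution with 'same' zero padding.

    ``x`` is (C_in, H, W), ``weight`` is (C_out, C_in, k, k), ``bias`` (C_out,).
    Implemented as k*k shifted matmuls, which is fast at the pair-matrix
    sizes this package uses (H = W = N <= a few dozen).
    """
    x = Tensor.as_tensor(x)
    ci, h, w = x.shape
    co = weight.shape[0]
    p = kernel // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    out = np.zeros((co, h, w))
    for i in range(kernel):
        for j in range(kernel):
            win = xp[:, i : i + h, j : j + w].reshape(ci, h * w)
            out += (weight.data[:, :, i, j] @ win).reshape(co, h, w)
    out += bias.data[:, None, None]

    def backward(g):
        gf = g.reshape(co, h * w)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(1, 2)))
        if weight.requires_grad or x.requires_grad:
            gx_p = np.zeros_like(xp)
            gw = np.zeros_like(weight.data)
            for i in range(kernel):
                for j in range(kernel):
                    win = xp[:, i : i + h, j : j + w].reshape(ci, h * w)
                    gw[:, :, i, j] = gf @ win.T
                    gx_p[:, i : i + h, j : j + w] += (weight.data[:, :, i, j].T @ gf).reshape(ci, h, w)
            if weight.requires_grad:
                weight._accum(gw)
            if x.requires_grad:
                x._accum(gx_p[:, p : p + h, p : p + w])

    parents = (x, weight, bias)
    res = Tensor(out)
    if any(t.requires_grad for t in parents):
        res.requires_grad = True
        res._prev = parents
        res._backward = backward
    return res


class Adam:
    """Adaptive-moment optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
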