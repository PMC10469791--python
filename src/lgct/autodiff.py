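"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network blocks in :mod:`lgct.model` are small enough that a compact
tape-based engine is sufficient: a :class:`Tensor` wraps an ndarray, every
operation records its parents and a backward closure, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

Tensors preserve float32/float64 input dtypes (anything else is promoted to
float64); python scalars do not promote. Broadcasting follows numpy
semantics; gradients of broadcast operands are reduced back to the operand
shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "einsum",
    "unfold",
    "pad_last",
    "softmax",
    "layer_norm",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self._grad_owned = False

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph traversal -----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference; a second contribution
        # allocates (the reference may be aliased by another node's grad)
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    @staticmethod
    def _make(data, parents, backward):
        needs = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=needs, parents=parents if needs else (),
                      backward=backward if needs else None)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            def bws(g):
                self._accum(g)

            return Tensor._make(self.data + other, (self,), bws)
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bws(g):
                self._accum(g * other)

            return Tensor._make(self.data * other, (self,), bws)
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, expo: float):
        out_data = self.data**expo

        def bw(g):
            self._accum(g * expo * self.data ** (expo - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            if other.requires_grad:
                other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(pos, self.data, neg_part)

        def bw(g):
            self._accum(g * np.where(pos, 1.0, neg_part + alpha))

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def _einsum_grad_spec(spec: str):
    lhs, out = spec.split("->")
    a_spec, b_spec = lhs.split(",")
    return a_spec, b_spec, out


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum. Every index of each operand must appear in the
    output or in the other operand (true for all contractions used here)."""
    a, b = as_tensor(a), as_tensor(b)
    a_spec, b_spec, out_spec = _einsum_grad_spec(spec)
    out_data = np.einsum(spec, a.data, b.data, optimize=True)

    def bw(g):
        if a.requires_grad:
            a._accum(np.einsum(f"{out_spec},{b_spec}->{a_spec}", g, b.data,
                               optimize=True))
        if b.requires_grad:
            b._accum(np.einsum(f"{out_spec},{a_spec}->{b_spec}", g, a.data,
                               optimize=True))

    return Tensor._make(out_data, (a, b), bw)


def unfold(x: Tensor, size: int, stride: int = 1) -> Tensor:
    """Sliding windows over the last axis.

    (..., L) -> (..., L_out, size) with L_out = (L - size)//stride + 1.
    """
    x = as_tensor(x)
    L = x.data.shape[-1]
    n_out = (L - size) // stride + 1
    if n_out < 1:
        raise ValueError(f"window size {size} exceeds axis length {L}")
    view = np.lib.stride_tricks.sliding_window_view(x.data, size, axis=-1)
    out_data = view[..., ::stride, :]  # strided view; consumers may copy

    def bw(g):
        full = np.zeros_like(x.data)
        for k in range(size):
            full[..., k : k + (n_out - 1) * stride + 1 : stride] += g[..., :, k]
        x._accum(full)

    return Tensor._make(out_data, (x,), bw)


def pad_last(x: Tensor, left: int, right: int, value: float = 0.0) -> Tensor:
    x = as_tensor(x)
    pad = [(0, 0)] * (x.data.ndim - 1) + [(left, right)]
    out_data = np.pad(x.data, pad, constant_values=value)

    def bw(g):
        sl = [slice(None)] * g.ndim
        sl[-1] = slice(left, g.shape[-1] - right if right else None)
        x._accum(g[tuple(sl)])

    return Tensor._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-max-stabilised softmax, fused into a single op."""
    x = as_tensor(x)
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(x.data - shift)
    w = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        # d/dx softmax: w * (g - sum(g * w))
        x._accum(w * (g - (g * w).sum(axis=axis, keepdims=True)))

    return Tensor._make(w, (x,), bw)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalise over the last axis, then apply learned gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / (var + eps).sqrt() * gain + bias


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = ((rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
    return x * Tensor(mask)
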