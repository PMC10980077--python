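"""A small reverse-mode automatic-differentiation core over numpy arrays.

Implements exactly the operations the transformer encoder needs: broadcasted
arithmetic, (batched) matmul, a restricted two-operand einsum, integer-array
gather (embeddings), softmax, layer normalization, ReLU and reductions.
Gradients are accumulated on leaf tensors created with ``requires_grad=True``
via :meth:`Tensor.backward`, which runs the tape in reverse topological
order.  All arithmetic is float64; every op's gradient is covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "matmul",
    "einsum2",
    "take",
    "relu",
    "softmax",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (
                self._accum(_unbroadcast(g, self.data.shape))
                if self.requires_grad
                else None,
                other._accum(_unbroadcast(g, other.data.shape))
                if other.requires_grad
                else None,
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(
            -self.data,
            (self,),
            lambda g: self._accum(-g) if self.requires_grad else None,
        )

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                self._accum(_unbroadcast(g * other.data, self.data.shape))
                if self.requires_grad
                else None,
                other._accum(_unbroadcast(g * self.data, other.data.shape))
                if other.requires_grad
                else None,
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accum(_unbroadcast(g / other.data, self.data.shape))
                if self.requires_grad
                else None,
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )
                if other.requires_grad
                else None,
            ),
        )
        return out

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor._make(
            self.data**e,
            (self,),
            lambda g: self._accum(g * e * self.data ** (e - 1))
            if self.requires_grad
            else None,
        )
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor._make(
            self.data.reshape(*shape),
            (self,),
            lambda g: self._accum(g.reshape(old)) if self.requires_grad else None,
        )
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor._make(
            self.data.transpose(*axes),
            (self,),
            lambda g: self._accum(g.transpose(*inv)) if self.requires_grad else None,
        )
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(
            out_data,
            (self,),
            lambda g: self._accum(g * out_data) if self.requires_grad else None,
        )

    def log(self):
        return Tensor._make(
            np.log(self.data),
            (self,),
            lambda g: self._accum(g / self.data) if self.requires_grad else None,
        )

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._make(a.data @ b.data, (a, b), backward)


def einsum2(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum whose operands' indices all appear in ``out + other``.

    That restriction (no index summed within a single operand) makes the
    gradient another einsum with permuted subscripts, which covers the
    attention/relative-embedding contractions used here.
    """
    a, b = as_tensor(a), as_tensor(b)
    inputs, out_sub = spec.replace(" ", "").split("->")
    a_sub, b_sub = inputs.split(",")
    if not (set(a_sub) <= set(out_sub) | set(b_sub)):
        raise ValueError(f"unsupported einsum spec {spec!r}")
    if not (set(b_sub) <= set(out_sub) | set(a_sub)):
        raise ValueError(f"unsupported einsum spec {spec!r}")

    def backward(g):
        if a.requires_grad:
            a._accum(np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data))
        if b.requires_grad:
            b._accum(np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data))

    return Tensor._make(np.einsum(spec, a.data, b.data), (a, b), backward)


def take(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``t[idx]``; backward scatter-adds into the table."""
    idx = np.asarray(idx)

    def backward(g):
        if t.requires_grad:
            gt = np.zeros_like(t.data)
            np.add.at(gt, idx, g)
            t._accum(gt)

    return Tensor._make(t.data[idx], (t,), backward)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g):
        if t.requires_grad:
            t._accum(g * mask)

    return Tensor._make(t.data * mask, (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            t._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor._make(y, (t,), backward)


def layer_norm(t: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean, unit variance (no affine)."""
    mu = t.data.mean(axis=-1, keepdims=True)
    var = t.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (t.data - mu) * inv

    def backward(g):
        if t.requires_grad:
            gm = g.mean(axis=-1, keepdims=True)
            gym = (g * y).mean(axis=-1, keepdims=True)
            t._accum(inv * (g - gm - y * gym))

    return Tensor._make(y, (t,), backward)
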