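"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Implements exactly the primitives the pair-transformer needs: broadcasting
arithmetic, batched matmul, reshape/transpose/concat, reductions, sin/cos,
ReLU/GELU, softmax, layer normalization, dropout, a per-feature linear map and
a numerically stable log-cosh.  Gradients are accumulated by a topological
backward sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ---- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # ---- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inverse))

        return Tensor._make(self.data.transpose(*axes), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ---- functional primitives --------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accumulate(full)

    return Tensor._make(x.data[idx], (x,), backward)


def sin(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.cos(x.data))

    return Tensor._make(np.sin(x.data), (x,), backward)


def cos(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(-g * np.sin(x.data))

    return Tensor._make(np.cos(x.data), (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, tanh approximation."""
    c = np.sqrt(2.0 / np.pi)
    u = c * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    y = 0.5 * x.data * (1.0 + t)

    def backward(g):
        if x.requires_grad:
            du = c * (1.0 + 3 * 0.044715 * x.data**2)
            dy = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du
            x._accumulate(g * dy)

    return Tensor._make(y, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean, unit variance (no affine)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv

    def backward(g):
        if x.requires_grad:
            x._accumulate(
                inv
                * (
                    g
                    - g.mean(axis=-1, keepdims=True)
                    - y * (g * y).mean(axis=-1, keepdims=True)
                )
            )

    return Tensor._make(y, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def feature_linear(a: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Per-feature affine map: (B, n, k) x (n, k, d) + (n, d) -> (B, n, d).

    Row i of the output uses only feature i's own weights; nothing is shared
    across features.
    """
    y = np.einsum("bnk,nkd->bnd", a.data, w.data) + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum("bnd,nkd->bnk", g, w.data))
        if w.requires_grad:
            w._accumulate(np.einsum("bnk,bnd->nkd", a.data, g))
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    return Tensor._make(y, (a, w, b), backward)


def logcosh(residual: Tensor) -> Tensor:
    """Elementwise log(cosh(u)), stabilized as |u| + log1p(e^{-2|u|}) - log 2."""
    u = residual.data
    au = np.abs(u)
    y = au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0)

    def backward(g):
        if residual.requires_grad:
            residual._accumulate(g * np.tanh(u))

    return Tensor._make(y, (residual,), backward)
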