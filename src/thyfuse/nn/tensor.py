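"""A compact reverse-mode autodiff engine on NumPy arrays.

Every value in the network is a :class:`Tensor` wrapping a float32 ndarray.
Operations build a graph of parent links and backward closures; calling
``backward()`` on a scalar loss runs the closures in reverse topological
order.  Only the operations the fusion model needs are implemented, each
fully vectorized so the arithmetic runs inside BLAS/ufunc loops.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "matmul",
    "relu",
    "gelu",
    "softmax",
    "layer_norm",
    "cross_entropy",
]

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / np.sqrt(2.0).astype(np.float32)
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        elif data.dtype != np.float32:
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        # iterative DFS: deep graphs would blow the recursion limit
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        if _GRAD_ENABLED and (self.requires_grad or other.requires_grad):
            out.requires_grad = True
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))

            out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * -1.0)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        if _GRAD_ENABLED and (self.requires_grad or other.requires_grad):
            out.requires_grad = True
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))

            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src_shape = self.data.shape
            out._backward = lambda g: self._accumulate(g.reshape(src_shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(
                np.ascontiguousarray(g.transpose(tuple(inv)))
            )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(np.ascontiguousarray(self.data[idx]))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bwd(g):
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)

            out._backward = _bwd
        return out

    def broadcast_to(self, shape) -> "Tensor":
        out = Tensor(np.broadcast_to(self.data, shape).copy())
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src = self.data.shape
            out._backward = lambda g: self._accumulate(_unbroadcast(g, src))
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            src_shape = self.data.shape

            def _bwd(g):
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, src_shape).copy())

            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data)
    if _GRAD_ENABLED and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (a, b)

        def _bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        out._backward = _bwd
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(np.ascontiguousarray(g[tuple(sl)]))

        out._backward = _bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0))
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        mask = x.data > 0
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out = Tensor(x.data * cdf)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data * x.data)
        local = cdf + x.data * pdf
        out._backward = lambda g: x._accumulate(g * local)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def _bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

        out._backward = _bwd
    return out


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-token normalization over the last (embedding) axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_std
    out = Tensor(xhat * weight.data + bias.data)
    if _GRAD_ENABLED and (x.requires_grad or weight.requires_grad or bias.requires_grad):
        out.requires_grad = True
        out._parents = (x, weight, bias)
        d = x.data.shape[-1]

        def _bwd(g):
            if weight.requires_grad:
                weight._accumulate(
                    (g * xhat).reshape(-1, d).sum(axis=0).reshape(weight.data.shape)
                )
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, d).sum(axis=0).reshape(bias.data.shape))
            if x.requires_grad:
                dxhat = g * weight.data
                m1 = dxhat.mean(axis=-1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
                x._accumulate((dxhat - m1 - xhat * m2) * inv_std)

        out._backward = _bwd
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (B, K) and int labels (B,)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    b = labels.shape[0]
    nll = -np.log(probs[np.arange(b), labels] + 1e-12)
    out = Tensor(np.float32(nll.mean()))
    if _GRAD_ENABLED and logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)

        def _bwd(g):
            grad = probs.copy()
            grad[np.arange(b), labels] -= 1.0
            logits._accumulate(grad * (float(g) / b))

        out._backward = _bwd
    return out
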