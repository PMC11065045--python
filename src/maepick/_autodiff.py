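"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the masked-autoencoder model and its
losses need: broadcast arithmetic, (batched) matmul, reductions,
reshape/transpose, token gather, concatenation, softmax, layer norm,
tanh/exp/sqrt/maximum. Gradients are accumulated float32; every op is
checked against finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autograd driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy()  # copy: g may alias another tensor's grad
        else:
            self.grad = self.grad + g

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def back(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), back)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out, (a, b), back)

    # ---- elementwise functions ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), back)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def back(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), back)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def back(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), back)

    def maximum(self, floor: float):
        """max(self, floor) with subgradient 1 where self > floor."""
        a = self
        mask = a.data > floor

        def back(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.maximum(a.data, floor), (a,), back)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g2, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(g):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), back)

    def __getitem__(self, idx):
        a = self

        def back(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), back)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def as_tensor(x) -> Tensor:
    """Wrap a value as a constant Tensor (no-op on Tensors)."""
    return _as_tensor(x)


def parameter(data) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    t = Tensor(data)
    t.requires_grad = True  # parameters are trainable even inside no_grad()
    return t


# ---- composite / fused ops ----------------------------------------------


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
    )


def gather_tokens(x: Tensor, index: np.ndarray) -> Tensor:
    """out[b, i, :] = x[b, index[b, i], :] for a (B, N, D) tensor."""
    x = _as_tensor(x)
    index = np.asarray(index)
    b_idx = np.arange(x.data.shape[0])[:, None]
    out = x.data[b_idx, index]

    def back(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (b_idx, index), g)
            x._accum(full)

    return Tensor._make(out, (x,), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    return Tensor._make(s, (x,), back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def back(g):
        if gamma.requires_grad:
            gamma._accum(
                _unbroadcast((g * xhat).astype(np.float32), gamma.data.shape)
            )
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            n = x.data.shape[-1]
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), back)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    x = _as_tensor(x)
    x2 = x.data * x.data
    u = _GELU_C * (x.data + 0.044715 * (x2 * x.data))
    t = np.tanh(u)
    out = 0.5 * x.data * (1.0 + t)

    def back(g):
        if x.requires_grad:
            du = _GELU_C * (1.0 + (3 * 0.044715) * x2)
            dx = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t * t) * du
            x._accum(g * dx)

    return Tensor._make(out, (x,), back)
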