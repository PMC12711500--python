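"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the style of the big frameworks: each op
builds a :class:`Tensor` holding the forward value and a closure that
propagates the upstream gradient to its parents.  Only the operations the
network actually needs are provided (broadcasted arithmetic, batched
matmul, reductions, reshapes, the usual activations, softmax/log-softmax,
layer normalization, sliding-window max pooling and inverted dropout).

The batched-matmul op doubles as the FLOP meter: under a
:func:`count_macs` context every matrix product adds its multiply-
accumulate count to the active counter.  Since convolutions and linear
layers are lowered to matmuls, that is exactly the "matrix products only"
accounting convention used for the architecture report.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "count_macs",
    "add",
    "mul",
    "matmul",
    "concat",
    "relu",
    "gelu",
    "silu",
    "softmax",
    "log_softmax",
    "layer_norm",
    "max_pool2d",
    "dropout",
]

_GRAD_ENABLED = True
_MAC_COUNTER: dict | None = None

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


@contextmanager
def no_grad():
    """Disable graph construction (inference / accounting runs)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextmanager
def count_macs():
    """Count multiply-accumulates of every matmul executed in the block.

    Yields a one-key dict ``{"macs": int}`` updated in place.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    box = {"macs": 0}
    _MAC_COUNTER = box
    try:
        yield box
    finally:
        _MAC_COUNTER = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "retains_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward
        self.retains_grad = False

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

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def retain_grad(self):
        self.retains_grad = True
        return self

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate gradients / tape as we go
            if not (node.requires_grad or node.retains_grad) and node is not self:
                node.grad = None
            node._backward = None
            node._parents = ()

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, _pow(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return _pow(self, p)

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def reshape(self, *shape):
        return _reshape(self, shape)

    def transpose(self, *axes):
        return _transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return _mean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    """Build an op result; records the tape only when grad is enabled."""
    if _GRAD_ENABLED and any(p.requires_grad or p._parents or p._backward for p in parents):
        return Tensor(data, _parents=tuple(parents), _backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def _pow(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    if _MAC_COUNTER is not None:
        k = a.data.shape[-1]
        _MAC_COUNTER["macs"] += int(out_data.size) * int(k)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def _transpose(a: Tensor, axes) -> Tensor:
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def _getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def _sum(a: Tensor, axis, keepdims) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def _mean(a: Tensor, axis, keepdims) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.data.size / out_data.size

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g / denom, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------

def relu(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    a = _as_tensor(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = (x * phi).astype(np.float32)

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        a._accumulate(g * (phi + x * pdf))

    return _make(out_data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x), the conv-unit activation."""
    a = _as_tensor(a)
    x = a.data
    sig = 1.0 / (1.0 + np.exp(-x))
    out_data = (x * sig).astype(np.float32)

    def backward(g):
        a._accumulate(g * sig * (1.0 + x * (1.0 - sig)))

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def backward(g):
        a._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def layer_norm(a, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis to zero mean / unit variance (no affine)."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out_data = xc * inv

    def backward(g):
        gm = g.mean(axis=-1, keepdims=True)
        gy = (g * out_data).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - out_data * gy))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------
# pooling / dropout
# ---------------------------------------------------------------------

def max_pool2d(a, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Sliding-window max over (B, C, H, W); padding uses -inf."""
    a = _as_tensor(a)
    x = a.data
    B, C, H, W = x.shape
    if padding:
        x = np.pad(
            x,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    win = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gx = np.zeros_like(x)
        ky, kx_ = np.divmod(arg, kernel)
        b_i, c_i, ho_i, wo_i = np.indices((B, C, Ho, Wo), sparse=False)
        rows = ho_i * stride + ky
        cols = wo_i * stride + kx_
        np.add.at(gx, (b_i, c_i, rows, cols), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        a._accumulate(gx)

    return _make(out_data.astype(np.float32), (a,), backward)


def dropout(a, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero with probability p, scale survivors by 1/(1-p)."""
    a = _as_tensor(a)
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(np.float32) / (1.0 - p)
    out_data = a.data * keep

    def backward(g):
        a._accumulate(g * keep)

    return _make(out_data, (a,), backward)
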