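"""Minimal reverse-mode autodiff on NumPy arrays.

Provides exactly the tensor operations the pipeline's two networks need --
dense and batched matmul, 1-D convolution and max pooling, ReLU, softmax,
layer normalization, mean pooling, and a fused softmax cross-entropy --
plus an Adam optimizer.  Everything is deterministic given the caller's
seeds and runs in float32 by default.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Tuple

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to the given (broadcast-source) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    if np.isscalar(b):
        a = _as_tensor(a)
        out = Tensor(a.data * b, a.requires_grad, (a,))
        out._backward = lambda g: a._accum(g * b)
        return out
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad or b._parents:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.shape))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, a.requires_grad, (a,))
    out._backward = lambda g: a._accum(g * mask)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), a.requires_grad, (a,))
    out._backward = lambda g: a._accum(g.reshape(a.shape))
    return out


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), a.requires_grad, (a,))
    out._backward = lambda g: a._accum(g.transpose(inv))
    return out


def mean(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.mean(axis=axis, keepdims=keepdims), a.requires_grad, (a,))
    n = a.shape[axis]

    def backward(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        a._accum(np.broadcast_to(gg, a.shape) / n)

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, a.requires_grad, (a,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum((g - dot) * y)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad or x._parents:
            gxhat = g * gamma.data
            m1 = gxhat.mean(axis=-1, keepdims=True)
            m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum((gxhat - m1 - xhat * m2) * inv)

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution: x [B, C, L], w [F, C, k], b [F]."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    k = w.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=2)  # B,C,L',k
    y = np.einsum("bclk,fck->bfl", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(y.astype(x.data.dtype), True, (x, w, b))

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("bfl,bclk->fck", g, cols, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad or x._parents:
            gx = np.zeros_like(x.data)
            lp = g.shape[2]
            for j in range(k):
                gx[:, :, j:j + lp] += np.einsum("bfl,fc->bcl", g, w.data[:, :, j],
                                                optimize=True)
            x._accum(gx)

    out._backward = backward
    return out


def maxpool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (trailing samples
    that do not fill a window are dropped)."""
    x = _as_tensor(x)
    b, c, l = x.shape
    lp = l // factor
    xt = x.data[:, :, : lp * factor].reshape(b, c, lp, factor)
    arg = xt.argmax(axis=-1)
    y = np.take_along_axis(xt, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, x.requires_grad, (x,))

    def backward(g):
        gx = np.zeros((b, c, lp, factor), dtype=x.data.dtype)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        full = np.zeros_like(x.data)
        full[:, :, : lp * factor] = gx.reshape(b, c, lp * factor)
        x._accum(full)

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of logits [B, K]."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = labels.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype), True, (logits,))

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(p * (g / n))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# parameters and optimization


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))


def xavier_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-lim, lim, size=shape))


def zeros(shape) -> Tensor:
    return parameter(np.zeros(shape))


def ones(shape) -> Tensor:
    return parameter(np.ones(shape))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
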