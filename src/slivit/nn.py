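"""Reverse-mode automatic differentiation and neural-network layers on numpy.

This is a deliberately small engine: float32 arrays, a ``Tensor`` node type
carrying a gradient and a backward closure, and exactly the primitives the
slice-tiled architecture needs (matmul, depthwise convolution, layer norm,
GELU, softmax, sigmoid, reductions, reshapes). Convolutions whose kernel
equals their stride are expressed as patch-reshape + matmul by the model
code; the only true convolution primitive is the stride-1 depthwise one.

Everything is CPU-bound BLAS work, so tensors are kept channels-last and
pointwise convolutions become row-major matrix products.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32)
        else:
            self.grad = self.grad + g

    def backward(self):
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not (req and _GRAD_ENABLED):
            return Tensor(data)
        return Tensor(data, requires_grad=True, _prev=tuple(parents), _backward=backward)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = np.transpose(self.data, axes)

        def backward(g):
            self._accumulate(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return tensors[0]._make(out_data, tuple(tensors), backward)


# -- nonlinearities ---------------------------------------------------------

def gelu(x: Tensor) -> Tensor:
    """GELU in its sigmoid form, x * sigmoid(1.702 x)."""
    xd = x.data
    with np.errstate(over="ignore"):  # exp overflow -> s saturates at 0
        s = 1.0 / (1.0 + np.exp(-1.702 * xd))
    out_data = xd * s

    def backward(g):
        x._accumulate(g * s * (1.0 + 1.702 * xd * (1.0 - s)))

    return x._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return x._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift per channel."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            axes = tuple(range(g.ndim - 1))
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate((dxhat - m1 - xhat * m2) * inv)

    return x._make(out_data, (x, gamma, beta), backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded 'same' depthwise convolution.

    x: (B, H, W, C); w: (K, K, C) with K odd; b: (C,).
    Implemented as K*K shifted multiply-accumulates, which beats im2col
    for the small channel counts used here.
    """
    B, H, W, C = x.data.shape
    K = w.data.shape[0]
    p = K // 2
    xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
    xp[:, p:p + H, p:p + W, :] = x.data
    out_data = np.empty((B, H, W, C), dtype=np.float32)
    out_data[:] = b.data
    for u in range(K):
        for v in range(K):
            out_data += w.data[u, v] * xp[:, u:u + H, v:v + W, :]

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            gf = np.ascontiguousarray(g)
            for u in range(K):
                for v in range(K):
                    gw[u, v] = np.einsum("bhwc,bhwc->c", gf, xp[:, u:u + H, v:v + W, :])
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(K):
                for v in range(K):
                    gxp[:, u:u + H, v:v + W, :] += w.data[u, v] * g
            x._accumulate(gxp[:, p:p + H, p:p + W, :])

    return x._make(out_data, (x, w, b), backward)


# -- losses -----------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross entropy on raw logits (numerically stable)."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.float32(loss.mean())
    n = z.size

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (s - t) / n)

    return logits._make(out_data, (logits,), backward)


def l1_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean absolute error."""
    t = np.asarray(targets, dtype=np.float32)
    d = pred.data - t
    out_data = np.float32(np.abs(d).mean())
    n = d.size

    def backward(g):
        pred._accumulate(g * np.sign(d) / n)

    return pred._make(out_data, (pred,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross entropy; logits (B, K), labels integer (B,)."""
    lab = np.asarray(labels)
    z = logits.data
    shifted = z - z.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=-1))
    out_data = np.float32((logZ - shifted[np.arange(len(lab)), lab]).mean())
    n = len(lab)

    def backward(g):
        p = np.exp(shifted)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(n), lab] -= 1.0
        logits._accumulate(g * p / n)

    return logits._make(out_data, (logits,), backward)


# -- modules ----------------------------------------------------------------

def trunc_normal(rng: np.random.Generator, shape, std=0.02) -> np.ndarray:
    """Normal(0, std) with draws clipped at two standard deviations."""
    return (np.clip(rng.standard_normal(shape), -2.0, 2.0) * std).astype(np.float32)


class Module:
    """Container base class with recursive parameter discovery."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state, strict=True):
        params = dict(self.named_parameters())
        if strict and set(params) != set(state):
            missing = set(params) - set(state)
            extra = set(state) - set(params)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, arr in state.items():
            if k not in params:
                continue
            if params[k].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {params[k].data.shape} vs {arr.shape}")
            params[k].data = np.asarray(arr, dtype=np.float32).copy()

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_dim, out_dim, rng, std=None, bias=True):
        # fan-in scaling keeps activation variance stable across widths
        if std is None:
            std = 1.0 / math.sqrt(in_dim)
        self.weight = Tensor(trunc_normal(rng, (in_dim, out_dim), std), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = x.matmul(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-6):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        return layer_norm(x, self.gamma, self.beta, self.eps)


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimizer.

    Defaults follow the convention used for transformer fine-tuning here:
    betas (0.9, 0.99), eps 1e-5, weight decay 0.01. ``lr`` and ``beta1``
    are plain attributes so a schedule can drive them per step.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.99), eps=1e-5, weight_decay=0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
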