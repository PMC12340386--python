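"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training stack in this package (two coupled conditional VAEs and a
regression CNN) needs gradients through a branching computation graph:
the vascular-pattern encoder feeds its own decoder, the thickness encoder
*and* the thickness decoder, and two KL terms tap the latent parameters.
Rather than hand-deriving the chain rule for that graph, every array
operation used by the models is a node with an explicit vector-Jacobian
product; `Tensor.backward()` accumulates gradients over a topological
sort. Correctness is pinned by finite-difference tests.

Only the operations the models need are implemented; shapes follow numpy
broadcasting and matmul is restricted to 2-D operands.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter",
    "add", "sub", "mul", "div", "neg", "pow_", "matmul",
    "exp", "log", "sigmoid", "leaky_relu",
    "sum_", "mean", "reshape", "transpose", "concat", "take",
    "upsample_repeat", "conv1d_circ", "bce_with_logits",
]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._vjps = vjps

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    def zero_grad(self):
        self.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, p):
        return pow_(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x):
    return Tensor(x, requires_grad=False)


def parameter(x):
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _node(data, parents, vjps):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents), vjps=tuple(vjps))


def _unbroadcast(g, shape):
    """Sum a broadcast gradient back down to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic ---------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.data.shape),
                  lambda g: _unbroadcast(g, b.data.shape)))


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data - b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.data.shape),
                  lambda g: _unbroadcast(-g, b.data.shape)))


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 (lambda g: _unbroadcast(g * b.data, a.data.shape),
                  lambda g: _unbroadcast(g * a.data, b.data.shape)))


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data / b.data, (a, b),
                 (lambda g: _unbroadcast(g / b.data, a.data.shape),
                  lambda g: _unbroadcast(-g * a.data / b.data ** 2, b.data.shape)))


def neg(a):
    a = _as_tensor(a)
    return _node(-a.data, (a,), (lambda g: -g,))


def pow_(a, p):
    a = _as_tensor(a)
    p = float(p)
    return _node(a.data ** p, (a,), (lambda g: g * p * a.data ** (p - 1),))


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(a.data @ b.data, (a, b),
                 (lambda g: g @ b.data.T,
                  lambda g: a.data.T @ g))


# -- elementwise nonlinearities -----------------------------------------

def exp(a):
    a = _as_tensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), (lambda g: g * out,))


def log(a):
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), (lambda g: g / a.data,))


def sigmoid(a):
    a = _as_tensor(a)
    out = _sigmoid(a.data)
    return _node(out, (a,), (lambda g: g * out * (1.0 - out),))


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def leaky_relu(a, alpha=0.1):
    a = _as_tensor(a)
    slope = np.where(a.data > 0, 1.0, alpha)
    return _node(a.data * slope, (a,), (lambda g: g * slope,))


# -- reductions / shape -------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return _node(out, (a,), (vjp,))


def mean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = _as_tensor(a)
    return _node(a.data.reshape(shape), (a,),
                 (lambda g: g.reshape(a.data.shape),))


def transpose(a, axes):
    a = _as_tensor(a)
    inv = np.argsort(axes)
    return _node(a.data.transpose(axes), (a,),
                 (lambda g: g.transpose(inv),))


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def make_vjp(i):
        def vjp(g):
            return np.split(g, splits, axis=axis)[i]
        return vjp

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def take(a, idx):
    """Gather along the last axis: y = a[..., idx].

    `idx` may be any integer ndarray; the output shape is
    a.shape[:-1] + idx.shape. Powers circular padding, im2col patch
    extraction and nearest-neighbour upsampling.
    """
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = a.data[..., idx]
    L = a.data.shape[-1]
    lead = int(np.prod(a.data.shape[:-1])) if a.data.ndim > 1 else 1

    def vjp(g):
        gx = np.zeros((lead, L), dtype=np.float64)
        gflat = g.reshape(lead, idx.size)
        np.add.at(gx, (np.arange(lead)[:, None], idx.reshape(1, -1)), gflat)
        return gx.reshape(a.data.shape)

    return _node(out, (a,), (vjp,))


def upsample_repeat(a, factor):
    """(B, L, C) -> (B, L*factor, C) by nearest-neighbour repetition along
    the spatial axis."""
    a = _as_tensor(a)
    B, L, C = a.data.shape
    out = np.repeat(a.data, factor, axis=1)

    def vjp(g):
        return g.reshape(B, L, factor, C).sum(axis=2)

    return _node(out, (a,), (vjp,))


def conv1d_circ(x, W, b, stride, kernel):
    """Circularly padded 1-D convolution as a single fused graph node.

    Signals are channels-last: x (B, L, C); W (K*C, F) with rows ordered
    kernel-major (k0c0..k0c{C-1}, k1c0, ...); b (F,). Output
    (B, ceil(L/stride), F). The channels-last layout makes the im2col
    patch tensor contiguous, so forward and both weight/input gradients
    are single GEMMs plus a K-pass scatter (positions are distinct within
    each kernel offset, so plain fancy-index adds apply).
    """
    x, W, b = _as_tensor(x), _as_tensor(W), _as_tensor(b)
    B, L, C = x.data.shape
    K = kernel
    starts = np.arange(0, L, stride)
    offs = np.arange(K) - K // 2
    idx = (starts[:, None] + offs[None, :]) % L          # (L_out, K)
    Lo = len(starts)
    patches = x.data[:, idx, :]                          # (B, L_out, K, C)
    flat = patches.reshape(B * Lo, K * C)
    out = (flat @ W.data + b.data).reshape(B, Lo, -1)

    def vjp_x(g):
        gp = (g.reshape(B * Lo, -1) @ W.data.T).reshape(B, Lo, K, C)
        gx = np.zeros_like(x.data)
        for k in range(K):
            gx[:, (starts + offs[k]) % L, :] += gp[:, :, k, :]
        return gx

    def vjp_W(g):
        return flat.T @ g.reshape(B * Lo, -1)

    return _node(out, (x, W, b),
                 (vjp_x, vjp_W, lambda g: g.sum(axis=(0, 1))))


def bce_with_logits(logits, targets):
    """Elementwise binary cross-entropy from logits, numerically stable.

    loss = max(x, 0) - x*t + log(1 + exp(-|x|)); d/dx = sigmoid(x) - t.
    `targets` is a plain array (no gradient flows to it).
    """
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=np.float64)
    x = logits.data
    out = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    return _node(out, (logits,), (lambda g: g * (_sigmoid(x) - t),))
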