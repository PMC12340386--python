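"""Neural-network layers on the autograd core.

Profiles live on a closed circle, so every convolution pads circularly
along the spatial (angular) axis; there is no boundary. Downsampling is
strided convolution, upsampling is nearest-neighbour repetition followed
by a stride-1 circular convolution (a checkerboard-free stand-in for a
transposed convolution). Signals are channels-last, (batch, length,
channels), which keeps every im2col patch tensor contiguous.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursive parameter collection."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)


class Dense(Module):
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = ag.parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = ag.parameter(np.zeros(n_out))

    def __call__(self, x):
        return ag.add(ag.matmul(x, self.W), self.b)


class Conv1dCirc(Module):
    """1-D convolution with circular padding, implemented via im2col.

    Channels-last: input (B, L, C) -> output (B, ceil(L / stride), C_out).
    """

    def __init__(self, c_in, c_out, kernel=5, stride=1, rng=None):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = ag.parameter(rng.normal(0.0, scale, size=(kernel * c_in, c_out)))
        self.b = ag.parameter(np.zeros(c_out))

    def __call__(self, x):
        if x.shape[2] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[2]}")
        return ag.conv1d_circ(x, self.W, self.b, self.stride, self.kernel)


def upsample_nearest(x, factor=2):
    """(B, L, C) -> (B, L*factor, C) by sample repetition."""
    return ag.upsample_repeat(x, factor)


def flatten(x):
    B = x.shape[0]
    return ag.reshape(x, (B, int(np.prod(x.shape[1:]))))


class Dropout(Module):
    """Inverted dropout; a no-op unless `training` is passed at call time."""

    def __init__(self, p=0.5):
        self.p = p

    def __call__(self, x, rng=None, training=False):
        if not training or self.p <= 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return ag.mul(x, ag.constant(mask))


class ConvEncoder1d(Module):
    """Stack of strided circular conv blocks with LeakyReLU; returns the
    flattened feature map (the h-vector tapped as a coupling condition)."""

    def __init__(self, c_in, channels, kernel, rng, alpha=0.1):
        self.alpha = alpha
        self.blocks = []
        prev = c_in
        for c in channels:
            self.blocks.append(Conv1dCirc(prev, c, kernel=kernel, stride=2, rng=rng))
            prev = c

    def __call__(self, x):
        h = x
        for blk in self.blocks:
            h = ag.leaky_relu(blk(h), self.alpha)
        return flatten(h)


class ConvDecoder1d(Module):
    """FC stem -> repeated (upsample x2 + circular conv) blocks -> 1 channel.

    Produces a length-`length` signal (linear output; callers apply a
    sigmoid for binary targets).
    """

    def __init__(self, n_in, length, channels, kernel, rng, alpha=0.1, fc_width=64):
        self.alpha = alpha
        self.length = length
        n_up = len(channels)
        self.l0 = length // (2 ** n_up)
        if self.l0 * 2 ** n_up != length:
            raise ValueError("profile length must be divisible by 2**len(channels)")
        self.c0 = channels[0]
        self.fc1 = Dense(n_in, fc_width, rng)
        self.fc2 = Dense(fc_width, self.l0 * self.c0, rng)
        self.blocks = []
        prev = self.c0
        for c in list(channels[1:]) + [1]:
            self.blocks.append(Conv1dCirc(prev, c, kernel=kernel, stride=1, rng=rng))
            prev = c

    def __call__(self, z, rng=None, training=False, dropout=None):
        h = ag.leaky_relu(self.fc1(z), self.alpha)
        if dropout is not None:
            h = dropout(h, rng=rng, training=training)
        h = ag.leaky_relu(self.fc2(h), self.alpha)
        B = z.shape[0]
        h = ag.reshape(h, (B, self.l0, self.c0))
        for i, blk in enumerate(self.blocks):
            h = upsample_nearest(h, 2)
            h = blk(h)
            if i < len(self.blocks) - 1:
                h = ag.leaky_relu(h, self.alpha)
        return ag.reshape(h, (B, self.length))
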