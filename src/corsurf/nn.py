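"""Minimal 3D convolutional network engine (numpy, explicit backprop).

Implements exactly the blocks the reconstruction networks need — 3x3x3 and
1x1x1 convolutions, leaky ReLU, 2x2x2 max pooling, 2x nearest-neighbor
upsampling, channel concatenation — as layers with hand-derived gradients,
plus an Adam optimizer.  Convolutions use an im2col layout so the heavy
lifting is BLAS matrix products.  Arrays are float32, channel-first
``(C, D, H, W)``, single sample; batches are accumulated by the trainer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv3d",
    "LeakyReLU",
    "MaxPool3d",
    "Upsample3d",
    "Adam",
]


class Parameter:
    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Conv3d:
    """Same-padding 3D convolution, kernel 3 or 1, stride 1."""

    def __init__(self, in_channels, out_channels, kernel=3, rng=None, init_scale=None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel**3
        scale = np.sqrt(2.0 / fan_in) if init_scale is None else init_scale
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, fan_in)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        self._cols = None
        self._shape = None

    def params(self):
        return [self.weight, self.bias]

    def _im2col(self, x):
        if self.k == 1:
            c, d, h, w = x.shape
            return x.reshape(c, -1).T
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        v = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, D, H, W, 3,3,3)
        return np.ascontiguousarray(v.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            -1, self.cin * 27
        )

    def forward(self, x, train=True):
        cols = self._im2col(x)
        y = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cols = cols
            self._shape = x.shape
        d, h, w = x.shape[1:]
        return y.T.reshape(self.cout, d, h, w)

    def backward(self, g):
        d, h, w = self._shape[1:]
        g2 = g.reshape(self.cout, -1).T  # (N, cout)
        self.weight.grad += (g2.T @ self._cols).astype(np.float32)
        self.bias.grad += g2.sum(axis=0).astype(np.float32)
        if self.k == 1:
            dx = (g2 @ self.weight.value).T.reshape(self._shape)
        else:
            # transposed conv = conv of g with spatially flipped kernels,
            # input/output channels swapped
            wt = self.weight.value.reshape(self.cout, self.cin, 3, 3, 3)
            wt = wt[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            wt = np.ascontiguousarray(wt).reshape(self.cin, self.cout * 27)
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
            v = sliding_window_view(gp, (3, 3, 3), axis=(1, 2, 3))
            gcols = np.ascontiguousarray(v.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
                -1, self.cout * 27
            )
            dx = (gcols @ wt.T).T.reshape(self._shape)
        self._cols = None
        return dx


class LeakyReLU:
    def __init__(self, alpha=0.01):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class MaxPool3d:
    """2x2x2 max pooling, stride 2; input spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x, train=True):
        c, d, h, w = x.shape
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = np.ascontiguousarray(blocks.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            c, d // 2, h // 2, w // 2, 8
        )
        idx = blocks.argmax(axis=-1)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        c, d, h, w = self._shape
        out = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        return np.ascontiguousarray(out.transpose(0, 1, 4, 2, 5, 3, 6)).reshape(
            c, d, h, w
        )


class Upsample3d:
    """2x nearest-neighbor upsampling."""

    def params(self):
        return []

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        c, d, h, w = self._shape
        return (
            g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)).astype(g.dtype)
        )


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
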