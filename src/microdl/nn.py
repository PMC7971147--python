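"""Minimal CPU neural-network engine.

Layers operate on ``(N, C, H, W)`` float32 arrays and implement explicit
forward/backward passes; there is no autograd graph. Each layer caches what its
backward pass needs during ``forward``, so a layer instance supports one
forward/backward pair at a time (sufficient for plain SGD-style training loops).

Parameters are named (``block.conv1.weight`` style) so that checkpoints can be
matched layer-by-layer for transfer learning.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Adam",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer. Subclasses define forward(x, training) and backward(dy)."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2D convolution with zero 'same' padding for stride 1, bias included.

    For stride > 1 the padding is k//2 on each side (the standard residual-net
    downsampling convention).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                                f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (xp.shape[2] - k) // s + 1
        ow = (xp.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wmat = self.weight.value.reshape(self.out_ch, c * k * k)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape, xp.shape, oh, ow)
        return np.ascontiguousarray(
            y.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, xshape, xpshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s = self.k, self.stride
        p = k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        wmat = self.weight.value.reshape(self.out_ch, c * k * k)
        self.weight.grad += (dyf.T @ cols).reshape(self.weight.shape)
        self.bias.grad += dyf.sum(axis=0)
        dcols = (dyf @ wmat).reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xpshape, dtype=np.float32)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + s * oh:s, v:v + s * ow:s] += dcols[:, :, :, :, u, v]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None, name: str = "upconv"):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch),
                                f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        # y[n,o,2i+u,2j+v] = sum_c W[c,o,u,v] x[n,c,i,j]
        t = np.einsum("couv,ncij->noiujv", self.weight.value, x, optimize=True)
        y = t.reshape(n, self.out_ch, 2 * h, 2 * w) + self.bias.value[None, :, None, None]
        self._cache = (x, (n, c, h, w))
        return y

    def backward(self, dy):
        x, (n, c, h, w) = self._cache
        dyr = dy.reshape(n, self.out_ch, h, 2, w, 2)    # (n,o,i,u,j,v)
        self.weight.grad += np.einsum("noiujv,ncij->couv", dyr, x, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("couv,noiujv->ncij", self.weight.value, dyr, optimize=True)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_dim, out_dim), in_dim), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32), f"{name}.bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling (even spatial dims required)."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xr = x.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, hh, ww, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        hh, ww = h // 2, w // 2
        d = np.zeros((n, c, hh, ww, 4), dtype=np.float32)
        np.put_along_axis(d, self._idx[..., None], dy[..., None], axis=-1)
        return d.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; active when ``training`` is True.

    At inference the Monte-Carlo caller re-invokes forward with training=True to
    keep the stochastic units live. ``rng`` may be reseated at any time.
    """

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
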