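"""Minimal seeded convolutional-network engine used by the cGAN.

Implements exactly the layers the generator and discriminator need —
strided convolution, strided transposed convolution, leaky ReLU / ReLU /
tanh, dropout, a dense head with softmax — with manual backpropagation and
an Adam optimizer.  Tensors follow the (N, C, H, W) layout in float32.

Convolutions use a 4x4 kernel with stride 2 and padding 1 throughout, the
pix2pix convention: each encoder stage halves and each decoder stage
doubles the spatial resolution.  All randomness (weight initialisation,
dropout masks, shuffling) flows through explicit ``numpy.random.Generator``
objects so training is bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Dropout",
    "Adam",
    "softmax",
    "im2col",
    "col2im",
]

_INIT_SD = 0.02  # weight init scale, pix2pix convention


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N,C,H,W) into (N, C*k*k, Ho*Wo) patch columns."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, c: int, h: int, w: int, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`; returns (N,C,H,W)."""
    n = cols.shape[0]
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols6[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base layer: forward caches what backward needs; params are (name, array) pairs."""

    def params(self) -> list[tuple[str, np.ndarray]]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """4x4 stride-2 convolution with padding 1 (halves H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1) -> None:
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.w = rng.normal(0.0, _INIT_SD, (out_ch, in_ch * k * k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=True):
        self._in_shape = x.shape
        cols = im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        n = x.shape[0]
        ho = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        wo = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        y = np.matmul(self.w, cols) + self.b[:, None]
        return y.reshape(n, self.out_ch, ho, wo)

    def backward(self, gy):
        n, _, ho, wo = gy.shape
        gyf = gy.reshape(n, self.out_ch, ho * wo)
        self.gw += np.einsum("nol,ncl->oc", gyf, self._cols, optimize=True)
        self.gb += gyf.sum(axis=(0, 2))
        gcols = np.matmul(self.w.T, gyf)
        _, c, h, w = self._in_shape
        return col2im(gcols, c, h, w, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """4x4 stride-2 transposed convolution with padding 1 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1) -> None:
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.w = rng.normal(0.0, _INIT_SD, (in_ch, out_ch * k * k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x_flat: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.gw, self.gb]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        ho = self.stride * (h - 1) + self.k - 2 * self.pad
        wo = self.stride * (w - 1) + self.k - 2 * self.pad
        return ho, wo

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        xf = x.reshape(n, c, h * w)
        self._x_flat = xf
        cols = np.matmul(self.w.T, xf)  # (N, out*k*k, H*W)
        ho, wo = self._out_hw(h, w)
        y = col2im(cols, self.out_ch, ho, wo, self.k, self.stride, self.pad)
        return y + self.b[None, :, None, None]

    def backward(self, gy):
        n, c, h, w = self._in_shape
        gcols = im2col(gy, self.k, self.stride, self.pad)  # (N, out*k*k, H*W)
        self.gw += np.einsum("nil,nkl->ik", self._x_flat, gcols, optimize=True)
        self.gb += gy.sum(axis=(0, 2, 3))
        gx = np.matmul(self.w, gcols)
        return gx.reshape(n, c, h, w)


class Dense(Layer):
    """Fully connected layer on flattened features."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        self.w = rng.normal(0.0, _INIT_SD, (out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, train=True):
        self._in_shape = x.shape
        xf = x.reshape(x.shape[0], -1)
        self._x = xf
        return xf @ self.w.T + self.b

    def backward(self, gy):
        self.gw += gy.T @ self._x
        self.gb += gy.sum(axis=0)
        return (gy @ self.w).reshape(self._in_shape)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._x: np.ndarray | None = None

    def forward(self, x, train=True):
        self._x = x
        return np.where(x > 0, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._x > 0, gy, self.slope * gy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Layer):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y * self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise InvalidArgumentError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam over a list of (param, grad) pairs with shared hyperparameters."""

    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.pairs = pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0
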