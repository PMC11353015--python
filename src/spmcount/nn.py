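"""Minimal NumPy neural-network engine (NCHW, float64 by default).

Provides exactly the layer set needed by the particle-count classifiers:
standard and depthwise convolutions (im2col-based, 'same' padding, arbitrary
stride), batch normalization, squeeze-and-excitation, ReLU/SiLU, max and
global-average pooling, dense layers, a residual wrapper, softmax
cross-entropy and an Adam optimizer.  Every layer implements an analytic
backward pass; correctness is pinned by finite-difference gradient checks in
the test suite.

Design notes: forward caches live on the layer instance, so a layer object
belongs to one network and one in-flight batch at a time.  Backward through
a convolution is itself a convolution: the incoming gradient is zero-stuffed
by the stride, padded, and correlated with the spatially flipped, channel-
transposed kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Sequential", "Residual", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "Dense", "ReLU", "SiLU", "Sigmoid", "MaxPool2d",
    "GlobalAvgPool", "SqueezeExcite", "softmax", "softmax_cross_entropy",
    "Adam", "param_count",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype=np.float64) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Layer:
    """Base class: parameters, gradients and forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> window tensor (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _stuff_and_pad(dy: np.ndarray, stride: int, pad: int,
                   out_hw: tuple[int, int]) -> np.ndarray:
    """Zero-stuff a gradient by the forward stride, then zero-pad by `pad`."""
    n, c, h, w = dy.shape
    if stride > 1:
        full = np.zeros((n, c, out_hw[0], out_hw[1]), dtype=dy.dtype)
        full[:, :, ::stride, ::stride] = dy
        dy = full
    if pad:
        dy = np.pad(dy, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return dy


class Conv2d(Layer):
    """k x k convolution, 'same' zero padding (pad = k // 2), stride s."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.in_c, self.out_c, self.k, self.stride = in_c, out_c, k, stride
        self.pad = k // 2
        self.w = _he_init(rng, (out_c, in_c, k, k), in_c * k * k, dtype)
        self.b = np.zeros(out_c, dtype=dtype) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dw] + ([self.db] if self.db is not None else [])

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        win = _im2col(x, self.k, self.stride, self.pad)  # N,C,Ho,Wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        y = cols @ self.w.reshape(self.out_c, -1).T
        if self.b is not None:
            y += self.b
        if train:
            self._cache = (cols, (n, c, h, w), (ho, wo))
        return y.reshape(n, ho, wo, self.out_c).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (n, c, h, w), (ho, wo) = self._cache
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_c)
        self.dw[...] = (dyf.T @ cols).reshape(self.w.shape)
        if self.b is not None:
            self.db[...] = dyf.sum(axis=0)
        # dx: stuffed/padded dy correlated with flipped, transposed kernel
        stuffed_hw = (h + 2 * self.pad - self.k + 1, w + 2 * self.pad - self.k + 1)
        dyp = _stuff_and_pad(dy, self.stride, self.k - 1 - self.pad, stuffed_hw)
        wflip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # in_c,out_c,k,k
        win = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        dx = np.einsum("nohwij,coij->nchw", win, wflip, optimize=True)
        return dx


class DepthwiseConv2d(Layer):
    """Per-channel k x k convolution ('same' padding, stride s)."""

    def __init__(self, channels: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.c, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        self.w = _he_init(rng, (channels, k, k), k * k, dtype)
        self.dw = np.zeros_like(self.w)
        self._cache = None

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]

    def forward(self, x, train=False):
        win = _im2col(x, self.k, self.stride, self.pad)  # N,C,Ho,Wo,k,k
        y = np.einsum("nchwij,cij->nchw", win, self.w, optimize=True)
        if train:
            self._cache = (win, x.shape)
        return y

    def backward(self, dy):
        win, in_shape = self._cache
        self.dw[...] = np.einsum("nchwij,nchw->cij", win, dy, optimize=True)
        _, _, h, w = in_shape
        stuffed_hw = (h + 2 * self.pad - self.k + 1, w + 2 * self.pad - self.k + 1)
        dyp = _stuff_and_pad(dy, self.stride, self.k - 1 - self.pad, stuffed_hw)
        wflip = self.w[:, ::-1, ::-1]
        dwin = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        return np.einsum("nchwij,cij->nchw", dwin, wflip, optimize=True)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros(channels, dtype=dtype)
        self.dbeta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, m = self._cache
        axes = (0, 2, 3)
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dxhat = dy
        mean_d = dxhat.mean(axis=axes)[None, :, None, None]
        mean_dx = (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        return g * (dxhat - mean_d - xhat * mean_dx)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.w = _he_init(rng, (in_f, out_f), in_f, dtype)
        self.b = np.zeros(out_f, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class SiLU(Layer):
    """x * sigmoid(x) (the swish activation used throughout EfficientNet)."""

    def forward(self, x, train=False):
        s = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        return dy * (s * (1.0 + x * (1.0 - s)))


class Sigmoid(Layer):
    def forward(self, x, train=False):
        s = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._s = s
        return s

    def backward(self, dy):
        return dy * self._s * (1.0 - self._s)


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (inputs must have even H, W)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        if train:
            self._mask = r == y[:, :, :, None, :, None]
            self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class SqueezeExcite(Layer):
    """Channel gating: GAP -> dense/ReLU -> dense/sigmoid -> scale."""

    def __init__(self, channels: int, reduced: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.fc1 = Dense(channels, reduced, rng, dtype)
        self.relu = ReLU()
        self.fc2 = Dense(reduced, channels, rng, dtype)
        self.sig = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def grads(self):
        return self.fc1.grads() + self.fc2.grads()

    def forward(self, x, train=False):
        s = x.mean(axis=(2, 3))
        g = self.sig(self.fc2(self.relu(self.fc1(s, train), train), train), train)
        if train:
            self._cache = (x, g)
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, g = self._cache
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        ds = self.fc1.backward(self.relu.backward(
            self.fc2.backward(self.sig.backward(dg))))
        _, _, h, w = x.shape
        dx += ds[:, :, None, None] / (h * w)
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Residual(Layer):
    """y = x + body(x); used when an MBConv block preserves shape."""

    def __init__(self, body: Layer):
        self.body = body

    def params(self):
        return self.body.params()

    def grads(self):
        return self.body.grads()

    def forward(self, x, train=False):
        return x + self.body.forward(x, train=train)

    def backward(self, dy):
        return dy + self.body.backward(dy)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam with optional cosine learning-rate decay over a known step budget."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 total_steps: int | None = None):
        self.params = params
        self.lr0, self.betas, self.eps = lr, betas, eps
        self.total_steps = total_steps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    @property
    def lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def param_count(model: Layer) -> int:
    return int(sum(p.size for p in model.params()))
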