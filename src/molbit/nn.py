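"""Minimal 1-D convolutional network layers on numpy.

Just enough machinery for the molbit signal classifier: Conv1D (same
padding, stride 1, via im2col + BLAS matmul), ReLU, average pooling,
batch normalization, dropout, dense layers, a softmax cross-entropy head
and Adam. Everything is deterministic given the Generator passed in, and
every layer implements ``forward(x, train)`` / ``backward(dy)`` with
parameter gradients accumulated in ``grads``.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) after flattening.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Stride-1 'same' 1-D convolution. Weights use He initialization."""

    def __init__(self, in_ch, out_ch, kernel, rng, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = (rng.standard_normal((in_ch * kernel, out_ch)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        B, C, L = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        # (B, C, L, k) -> (B, L, C, k) -> (B*L, C*k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C * k)
        self._cols, self._shape = cols, (B, C, L)
        y = cols @ self.W + self.b
        return np.ascontiguousarray(y.reshape(B, L, self.out_ch).transpose(0, 2, 1))

    def backward(self, dy):
        B, C, L = self._shape
        k = self.kernel
        pad = k // 2
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.out_ch)
        self.grads[0][...] = self._cols.T @ dy_flat
        self.grads[1][...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.T).reshape(B, L, C, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + k - 1), dtype=dy.dtype)
        for t in range(k):
            dxp[:, :, t : t + L] += dcols[:, :, :, t]
        return dxp[:, :, pad : pad + L]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool1D(Layer):
    """Non-overlapping average pooling; trailing remainder samples dropped."""

    def __init__(self, pool):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        B, C, L = x.shape
        p = self.pool
        Lo = L // p
        self._L = L
        return x[:, :, : Lo * p].reshape(B, C, Lo, p).mean(axis=3)

    def backward(self, dy):
        B, C, Lo = dy.shape
        p = self.pool
        dx = np.zeros((B, C, self._L), dtype=dy.dtype)
        dx[:, :, : Lo * p] = np.repeat(dy / p, p, axis=2)
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape[0] * x.shape[2], train)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv, m, train = self._cache
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None]
        if not train:
            return dy * g * inv[None, :, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return term * inv[None, :, None]


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
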