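"""Compact NumPy convolutional-network core.

Implements exactly the pieces the trail-segmentation network needs —
3x3/1x1 convolution (optionally strided), batch normalisation, leaky/plain
ReLU, 2x2 max-pooling, 2x2 stride-2 transposed convolution, skip
concatenation, a numerically stable sigmoid/binary-cross-entropy head and
the Adam optimiser — with explicit forward/backward passes. Data layout is
NHWC float32 throughout. Everything is seeded and single-threaded BLAS
deterministic: two builds/trainings from the same seed produce identical
parameters.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Array = np.ndarray


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: Array):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> Array:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    # state beyond trainable params (e.g. batch-norm running moments)
    def state(self) -> dict[str, Array]:
        return {}

    def load_state(self, state: dict[str, Array]) -> None:
        pass

    def forward(self, x: Array, train: bool) -> Array:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """KxK convolution, 'same' padding by default, optional stride.

    Weights are stored as ``(C_in * K * K, C_out)`` with row order matching
    the ``(C, kh, kw)`` layout of the im2col windows.
    """

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(he_normal(rng, (c_in * k * k, c_out), c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (n, ho, wo, c, k, k) -> flatten trailing (c, kh, kw)
        ho, wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win).reshape(n * ho * wo, -1)
        out = cols @ self.w.value + self.b.value
        self._cache = (cols, xp.shape, (n, h, w), (ho, wo))
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, g):
        cols, xp_shape, (n, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        g2 = g.reshape(n * ho * wo, self.c_out)
        self.w.grad += cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value.T).reshape(n, ho, wo, self.c_in, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * (ho - 1) + 1:s, j:j + s * (wo - 1) + 1:s, :] += \
                    dcols[:, :, :, :, i, j]
        if p:
            return dxp[:, p:p + h, p:p + w, :]
        return dxp


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def forward(self, x, train):
        axes = (0, 1, 2)
        if train:
            mu = x.mean(axes)
            var = x.var(axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, x.shape, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g):
        xhat, inv_std, shape, train = self._cache
        axes = (0, 1, 2)
        self.gamma.grad += (g * xhat).sum(axes)
        self.beta.grad += g.sum(axes)
        dxhat = g * self.gamma.value
        if not train:
            return dxhat * inv_std
        n = shape[0] * shape[1] * shape[2]
        return (inv_std / n) * (n * dxhat - dxhat.sum(axes)
                                - xhat * (dxhat * xhat).sum(axes))


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2. Input spatial dims must be even."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = np.ascontiguousarray(r.transpose(0, 1, 3, 5, 2, 4)).reshape(
            n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, h, w, c = self._shape
        gflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(gflat, self._idx[..., None], g[..., None], axis=-1)
        gr = gflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(gr).reshape(n, h, w, c)


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(he_normal(rng, (c_in, 2, 2, c_out), c_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, h, w, _ = x.shape
        self._x = x
        out = np.einsum("nhwc,cabo->nhawbo", x, self.w.value, optimize=True)
        return out.reshape(n, 2 * h, 2 * w, self.c_out) + self.b.value

    def backward(self, g):
        x = self._x
        n, h, w, _ = x.shape
        g6 = g.reshape(n, h, 2, w, 2, self.c_out)
        self.w.grad += np.einsum("nhwc,nhawbo->cabo", x, g6, optimize=True)
        self.b.grad += g.sum(axis=(0, 1, 2))
        return np.einsum("nhawbo,cabo->nhwc", g6, self.w.value, optimize=True)


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def sigmoid(x: Array) -> Array:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Array, targets: Array) -> float:
    """Mean binary cross-entropy of sigmoid(logits) vs. binary targets."""
    l, t = logits.astype(np.float64), targets.astype(np.float64)
    loss = np.maximum(l, 0) - l * t + np.log1p(np.exp(-np.abs(l)))
    return float(loss.mean())


def bce_logits_grad(logits: Array, targets: Array) -> Array:
    """d(mean BCE)/d(logits): (sigmoid(l) - t) / N."""
    return (sigmoid(logits) - targets.astype(np.float32)) / logits.size
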