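"""Minimal CPU neural-network engine used by the classifier families.

Plain-numpy layers with hand-written backward passes, an Adam optimiser and
a binary cross-entropy (with-logits) loss.  Convolutions are realised as
im2col + matmul so the heavy lifting lands in BLAS.  Everything is seeded
through explicit ``numpy.random.Generator`` objects; with a fixed seed a
forward/backward/update cycle is bit-reproducible on a given machine.

The engine is deliberately small: stride-1 "same" 1-D convolutions, the two
EEG-specific convolution types (channel-shared temporal and depthwise
spatial), pooling, dense layers, ReLU/ELU, dropout.  Each layer exposes
``params``/``grads`` lists of aligned arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "init_weights",
    "Layer",
    "Conv1d",
    "TemporalConv",
    "SpatialDepthwiseConv",
    "SeparableConv1d",
    "Dense",
    "ReLU",
    "ELU",
    "Dropout",
    "MaxPool1dSame",
    "AvgPoolDown",
    "GlobalAvgPool",
    "Flatten",
    "Adam",
    "bce_with_logits",
    "bce_grad",
    "sigmoid",
]

INIT_SCHEMES = ("glorot_uniform", "random_uniform", "random_normal")

#: Compute dtype for weights and activations.  float32 is the default for
#: training throughput; tests that compare against numerical derivatives
#: switch this to float64.
DTYPE = np.float32

# Spread of the non-Glorot initialisers; the distributions are part of the
# weight-randomisation ensemble design, the scale is a conventional default.
RANDOM_UNIFORM_LIMIT = 0.05
RANDOM_NORMAL_SD = 0.05


def init_weights(shape, fan_in, fan_out, scheme, rng: np.random.Generator):
    if scheme == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=shape)
    elif scheme == "random_uniform":
        w = rng.uniform(-RANDOM_UNIFORM_LIMIT, RANDOM_UNIFORM_LIMIT, size=shape)
    elif scheme == "random_normal":
        w = rng.normal(0.0, RANDOM_NORMAL_SD, size=shape)
    else:
        raise ValueError(f"unknown init scheme {scheme!r}; choose from {INIT_SCHEMES}")
    return w.astype(DTYPE)


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy from logits; stable for large |z|."""
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def bce_grad(z, y):
    return ((sigmoid(z) - y) / z.shape[0]).astype(z.dtype)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, *, train=False, rng=None, mc=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


def _same_pad(k):
    return (k - 1) // 2, k // 2


class Conv1d(Layer):
    """Stride-1 'same' 1-D convolution over [batch, channels, time]."""

    def __init__(self, c_in, c_out, k, scheme, rng, bias=True):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = init_weights((c_in * k, c_out), c_in * k, c_out, scheme, rng)
        self.b = np.zeros(c_out, dtype=DTYPE) if bias else None
        self.params = [self.W] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, **kw):
        B, C, T = x.shape
        pl, pr = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.k, axis=2)        # [B, C, T, k]
        self._win2 = win.transpose(0, 2, 1, 3).reshape(B, T, C * self.k)
        y = self._win2 @ self.W
        if self.b is not None:
            y += self.b
        self._xshape = x.shape
        return np.ascontiguousarray(y.transpose(0, 2, 1))   # [B, c_out, T]

    def backward(self, dy):
        B, _, T = dy.shape
        dy2 = dy.transpose(0, 2, 1)                          # [B, T, c_out]
        flat_w = self._win2.reshape(-1, self.c_in * self.k)
        self.grads[0][...] = flat_w.T @ dy2.reshape(-1, self.c_out)
        if self.b is not None:
            self.grads[1][...] = dy2.sum(axis=(0, 1))
        dwin = (dy2 @ self.W.T).reshape(B, T, self.c_in, self.k)
        dwin = dwin.transpose(0, 2, 1, 3)                    # [B, C, T, k]
        pl, pr = _same_pad(self.k)
        dxp = np.zeros((B, self.c_in, T + pl + pr), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j:j + T] += dwin[:, :, :, j]
        return dxp[:, :, pl:pl + T]


class TemporalConv(Layer):
    """Channel-shared temporal filters: [B, C, T] -> [B, F, C, T].

    Each of the F kernels slides along time and is applied identically to
    every channel (the first block of an EEGNet-style model).
    """

    def __init__(self, n_filters, k, scheme, rng):
        super().__init__()
        self.f, self.k = n_filters, k
        self.W = init_weights((k, n_filters), k, n_filters, scheme, rng)
        self.b = np.zeros(n_filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, **kw):
        B, C, T = x.shape
        pl, pr = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._win = sliding_window_view(xp, self.k, axis=2)  # [B, C, T, k]
        y = self._win @ self.W + self.b                      # [B, C, T, F]
        self._shape = (B, C, T)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        B, F, C, T = dy.shape
        dy2 = dy.transpose(0, 2, 3, 1)                       # [B, C, T, F]
        self.grads[0][...] = np.einsum("bctk,bctf->kf", self._win, dy2)
        self.grads[1][...] = dy2.sum(axis=(0, 1, 2))
        dwin = dy2 @ self.W.T                                # [B, C, T, k]
        pl, pr = _same_pad(self.k)
        dxp = np.zeros((B, C, T + pl + pr), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j:j + T] += dwin[:, :, :, j]
        return dxp[:, :, pl:pl + T]


class SpatialDepthwiseConv(Layer):
    """Depthwise spatial filters: [B, F, C, T] -> [B, F*D, T].

    For each temporal feature map, D spatial filters span all C channels and
    collapse the channel axis — the EEGNet depthwise convolution.
    """

    def __init__(self, n_temporal, depth_mult, n_channels, scheme, rng):
        super().__init__()
        self.f, self.d, self.c = n_temporal, depth_mult, n_channels
        self.W = init_weights((n_temporal, depth_mult, n_channels),
                              n_channels, depth_mult, scheme, rng)
        self.b = np.zeros(n_temporal * depth_mult, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, **kw):
        self._x = x
        B = x.shape[0]
        y = np.einsum("bfct,fdc->bfdt", x, self.W).reshape(B, self.f * self.d, -1)
        return y + self.b[None, :, None]

    def backward(self, dy):
        B, _, T = dy.shape
        dy4 = dy.reshape(B, self.f, self.d, T)
        self.grads[0][...] = np.einsum("bfct,bfdt->fdc", self._x, dy4)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        return np.einsum("bfdt,fdc->bfct", dy4, self.W)


class SeparableConv1d(Layer):
    """Depthwise temporal conv followed by a pointwise channel mix."""

    def __init__(self, c_in, c_out, k, scheme, rng):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.Wd = init_weights((c_in, k), k, 1, scheme, rng)
        self.Wp = init_weights((c_in, c_out), c_in, c_out, scheme, rng)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.Wd, self.Wp, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, **kw):
        B, C, T = x.shape
        pl, pr = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._win = sliding_window_view(xp, self.k, axis=2)   # [B, C, T, k]
        self._mid = np.einsum("bctk,ck->bct", self._win, self.Wd)
        y = np.einsum("bct,co->bot", self._mid, self.Wp) + self.b[None, :, None]
        self._shape = (B, C, T)
        return y

    def backward(self, dy):
        B, C, T = self._shape
        self.grads[2][...] = dy.sum(axis=(0, 2))
        self.grads[1][...] = np.einsum("bct,bot->co", self._mid, dy)
        dmid = np.einsum("bot,co->bct", dy, self.Wp)
        self.grads[0][...] = np.einsum("bctk,bct->ck", self._win, dmid)
        dwin = dmid[..., None] * self.Wd[None, :, None, :]    # [B, C, T, k]
        pl, pr = _same_pad(self.k)
        dxp = np.zeros((B, C, T + pl + pr), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, :, j:j + T] += dwin[:, :, :, j]
        return dxp[:, :, pl:pl + T]


class Dense(Layer):
    def __init__(self, n_in, n_out, scheme, rng):
        super().__init__()
        self.W = init_weights((n_in, n_out), n_in, n_out, scheme, rng)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, **kw):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, **kw):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ELU(Layer):
    def forward(self, x, **kw):
        self._neg = x <= 0
        self._expm = np.where(self._neg, np.exp(np.minimum(x, 0.0)) - 1.0, 0.0)
        return np.where(self._neg, self._expm, x)

    def backward(self, dy):
        return dy * np.where(self._neg, self._expm + 1.0, 1.0)


class Dropout(Layer):
    """Inverted dropout.

    ``mc_active=True`` marks the layer as participating in Monte Carlo
    dropout: it then also drops units at *inference* when the caller asks
    for a stochastic forward pass.
    """

    def __init__(self, rate, mc_active=False):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.mc_active = mc_active

    def forward(self, x, *, train=False, rng=None, mc=False, **kw):
        active = (train or (mc and self.mc_active)) and self.rate > 0.0
        if not active:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout needs an rng when active")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / x.dtype.type(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1dSame(Layer):
    """Stride-1 'same' max pooling along time (inception pool branch)."""

    def __init__(self, k=3):
        super().__init__()
        self.k = k

    def forward(self, x, **kw):
        B, C, T = x.shape
        pl, pr = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
        best = xp[:, :, 0:T].copy()
        arg = np.zeros((B, C, T), dtype=np.int8)
        for j in range(1, self.k):            # first-max wins ties (argmax rule)
            s = xp[:, :, j:j + T]
            m = s > best
            np.copyto(best, s, where=m)
            arg[m] = j
        self._arg = arg
        self._shape = (B, C, T)
        return best

    def backward(self, dy):
        B, C, T = self._shape
        pl, pr = _same_pad(self.k)
        dxp = np.zeros((B, C, T + pl + pr), dtype=dy.dtype)
        for j in range(self.k):
            sel = self._arg == j
            dxp[:, :, j:j + T] += dy * sel
        return dxp[:, :, pl:pl + T]


class AvgPoolDown(Layer):
    """Non-overlapping average pooling that downsamples time by ``k``."""

    def __init__(self, k):
        super().__init__()
        self.k = k

    def forward(self, x, **kw):
        B, C, T = x.shape
        self._T = T
        t = (T // self.k) * self.k
        self._t = t
        return x[:, :, :t].reshape(B, C, t // self.k, self.k).mean(axis=-1)

    def backward(self, dy):
        B, C, _ = dy.shape
        dx = np.zeros((B, C, self._T), dtype=dy.dtype)
        dx[:, :, :self._t] = np.repeat(dy, self.k, axis=2) / self.k
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, **kw):
        self._T = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._T, axis=2) / self._T


class Flatten(Layer):
    def forward(self, x, **kw):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Adam:
    def __init__(self, params, lr=0.005, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
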