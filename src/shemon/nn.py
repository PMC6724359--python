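"""Minimal 1-D convolutional network framework (numpy, explicit backprop).

Provides exactly the pieces the ECG segmentation and activity-recognition
networks need: strided same-padding Conv1D (im2col), batch normalization,
ReLU / linear activations, max pooling, nearest-neighbor upsampling, dense
layers, global average pooling, weighted categorical cross-entropy with
softmax, and Adam.  Tensors are ``(batch, length, channels)``.

All parameters are initialized from a caller-supplied ``numpy`` Generator, so
training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1D", "BatchNorm", "Activation", "MaxPool", "MaxPoolSame", "Upsample", "Dense",
    "GlobalAvgPool", "Adam", "softmax", "softmax_xent",
]


#: working precision of all layer parameters and activations
DTYPE = np.float32


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def _same_pad(L, k, s):
    Lout = -(-L // s)  # ceil
    total = max((Lout - 1) * s + k - L, 0)
    return Lout, total // 2, total - total // 2


class Conv1D(Layer):
    """Strided 1-D convolution with 'same' (ceil) padding."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None):
        self.k, self.s = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (kernel * c_in))
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, scale, size=(kernel * c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        N, L, C = x.shape
        Lout, pl, pr = _same_pad(L, self.k, self.s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        cols = sliding_window_view(xp, self.k, axis=1)  # (N, Lp-k+1, C, k)
        cols = cols[:, ::self.s, :, :][:, :Lout]
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))  # (N,Lout,k,C)
        self._cache = (cols, x.shape, pl, pr)
        out = cols.reshape(N * Lout, self.k * self.c_in) @ self.W + self.b
        return out.reshape(N, Lout, self.c_out)

    def backward(self, dy):
        cols, xshape, pl, pr = self._cache
        N, L, C = xshape
        Lout = dy.shape[1]
        dyf = dy.reshape(N * Lout, self.c_out)
        self.dW[...] = cols.reshape(N * Lout, self.k * C).T @ dyf
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(N, Lout, self.k, C)
        dxp = np.zeros((N, L + pl + pr, C), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, j:j + (Lout - 1) * self.s + 1:self.s, :] += dcols[:, :, j, :]
        return dxp[:, pl:pl + L, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros(c, dtype=DTYPE)
        self.dbeta = np.zeros(c, dtype=DTYPE)
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean *= self.momentum
            self.run_mean += (1 - self.momentum) * mean
            self.run_var *= self.momentum
            self.run_var += (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, m = self._cache
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return inv * (dxhat - dxhat.mean(axis=(0, 1))
                      - xhat * (dxhat * xhat).mean(axis=(0, 1)))


class Activation(Layer):
    def __init__(self, kind="relu"):
        if kind not in ("relu", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train=True):
        if self.kind == "linear":
            return x
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        if self.kind == "linear":
            return dy
        return dy * self._mask


class MaxPool(Layer):
    """Max pooling with ceil semantics (trailing window padded with -inf)."""

    def __init__(self, pool=2):
        self.p = pool

    def forward(self, x, train=True):
        N, L, C = x.shape
        Lout = -(-L // self.p)
        pad = Lout * self.p - L
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        xr = xp.reshape(N, Lout, self.p, C)
        self._arg = xr.argmax(axis=2)
        self._shape = (N, L, C, Lout, pad)
        return xr.max(axis=2)

    def backward(self, dy):
        N, L, C, Lout, pad = self._shape
        dxp = np.zeros((N, Lout, self.p, C))
        n_i, l_i, c_i = np.ogrid[:N, :Lout, :C]
        dxp[n_i, l_i, self._arg, c_i] = dy
        return dxp.reshape(N, Lout * self.p, C)[:, :L, :]


class MaxPoolSame(Layer):
    """Stride-1 max pooling with 'same' padding (inception pool branch)."""

    def __init__(self, k=3):
        self.k = k

    def forward(self, x, train=True):
        N, L, C = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.k, axis=1)  # (N, L, C, k)
        self._arg = win.argmax(axis=3)
        self._meta = (N, L, C, pl)
        return win.max(axis=3)

    def backward(self, dy):
        N, L, C, pl = self._meta
        dxp = np.zeros((N, L + self.k - 1, C))
        n_i, l_i, c_i = np.ogrid[:N, :L, :C]
        np.add.at(dxp, (n_i, l_i + self._arg, c_i), dy)
        return dxp[:, pl:pl + L, :]


class Upsample(Layer):
    """Nearest-neighbor upsampling along the length axis."""

    def __init__(self, factor=2):
        self.f = factor

    def forward(self, x, train=True):
        return np.repeat(x, self.f, axis=1)

    def backward(self, dy):
        N, L2, C = dy.shape
        return dy.reshape(N, L2 // self.f, self.f, C).sum(axis=2)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits, y, class_weights=None):
    """Softmax + weighted categorical cross-entropy.

    ``logits``: (n, K); ``y``: (n,) integer classes.  Returns
    (loss, dlogits, probs); the gradient is already averaged so it feeds
    straight into ``backward``.
    """
    n, K = logits.shape
    p = softmax(logits)
    w = np.ones(K) if class_weights is None else np.asarray(class_weights, float)
    wy = w[y]
    logp = np.log(p[np.arange(n), y] + 1e-300)
    loss = -(wy * logp).sum() / wy.sum()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (wy / wy.sum())[:, None]
    return loss, grad, p


class Adam:
    """Adam over a list of (param, grad) array pairs (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
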