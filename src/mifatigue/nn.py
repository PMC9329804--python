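"""Minimal NumPy neural-network layers with backpropagation.

Implements exactly the pieces the compact EEG classifier needs: 2-D
convolution (im2col + BLAS matmul forward, kernel-offset scatter
backward), batch normalization, ELU, average pooling, spatial (feature-
map) dropout, a dense layer, softmax cross-entropy, and Adam.  All
computation is float32 and fully deterministic given the seeds supplied
to layer construction and training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateSignalError


class Layer:
    """Base class: stateless unless it declares parameters."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs."""
        return []

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride and zero padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] = (0, 0),
                 rng: np.random.Generator | None = None,
                 input_grad: bool = True):
        rng = rng or np.random.default_rng()
        self.input_grad = input_grad  # False for the first layer: skip col2im
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.W = (rng.standard_normal((out_channels, in_channels, kh, kw))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.stride = stride
        self.padding = padding

    def output_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        c, h, w = in_shape
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        ph, pw = self.padding
        return (self.W.shape[0], (h + 2 * ph - kh) // sh + 1,
                (w + 2 * pw - kw) // sw + 1)

    def forward(self, x, training):
        n, c, h, w = x.shape
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        ho, wo = v.shape[2], v.shape[3]
        col = np.ascontiguousarray(
            v.transpose(0, 2, 3, 1, 4, 5)
        ).reshape(n, ho * wo, c * kh * kw)
        wm = self.W.reshape(self.W.shape[0], -1)
        out = col @ wm.T + self.b
        self._cache = (col, xp.shape, (ho, wo))
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(
            n, self.W.shape[0], ho, wo
        )

    def backward(self, grad):
        col, xp_shape, (ho, wo) = self._cache
        n = grad.shape[0]
        o = self.W.shape[0]
        g = np.ascontiguousarray(
            grad.reshape(n, o, ho * wo).transpose(0, 2, 1)
        )  # (n, HW, O)
        wm = self.W.reshape(o, -1)
        self.gW[...] = np.tensordot(g, col, axes=([0, 1], [0, 1])).reshape(
            self.W.shape
        )
        self.gb[...] = g.sum(axis=(0, 1))
        if not self.input_grad:
            return None
        gcol = g @ wm  # (n, HW, C*kh*kw)
        c = self.W.shape[1]
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        ph, pw = self.padding
        gv = gcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += \
                    gv[:, :, :, :, i, j]
        h = xp_shape[2] - 2 * ph
        w = xp_shape[3] - 2 * pw
        return gxp[:, :, ph : ph + h, pw : pw + w]

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class BatchNorm2d(Layer):
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + \
            self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        axes = (0, 2, 3)
        self.ggamma[...] = (grad * xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        gx = (self.gamma * inv)[None, :, None, None] / m * (
            m * grad
            - self.gbeta[None, :, None, None]
            - xhat * self.ggamma[None, :, None, None]
        )
        return gx.astype(np.float32)

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        y = np.where(x > 0, x, neg).astype(np.float32)
        self._cache = (x > 0, neg)
        return y

    def backward(self, grad):
        pos, neg = self._cache
        return grad * np.where(pos, 1.0, neg + self.alpha).astype(np.float32)


class AvgPool2d(Layer):
    """Non-overlapping average pooling (stride equals kernel)."""

    def __init__(self, kernel: tuple[int, int]):
        self.kernel = kernel

    def forward(self, x, training):
        n, c, h, w = x.shape
        kh, kw = self.kernel
        if h % kh or w % kw:
            raise DegenerateSignalError(
                f"pooling {self.kernel} does not tile input {h}x{w}"
            )
        self._in_shape = x.shape
        return x.reshape(n, c, h // kh, kh, w // kw, kw).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        kh, kw = self.kernel
        g = grad[:, :, :, None, :, None] / (kh * kw)
        return np.broadcast_to(
            g, (n, c, h // kh, kh, w // kw, kw)
        ).reshape(n, c, h, w).astype(np.float32)


class SpatialDropout2d(Layer):
    """Dropout of whole feature maps (channels), inverted scaling."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p)
        self._mask = keep.astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((out_features, in_features))
                  * np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.gW[...] = grad.T @ self._x
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam optimizer over (param, grad) pairs."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
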