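"""Minimal CPU neural-network layers with backpropagation.

Implements exactly the operations the two detection networks need —
2-D convolution (im2col + BLAS), max pooling, parametric ReLU,
AlexNet-style cross-channel local response normalization, sub-pixel
("double size") rearrangement, fully connected layers — plus the two
loss heads (per-cell logistic / 2-class softmax cross-entropy) and SGD
with momentum and weight decay.  Everything is float32, pure numpy, and
deterministic.

Array layout is ``(N, C, H, W)`` throughout.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "is_bias")

    def __init__(self, data: np.ndarray, is_bias: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.is_bias = is_bias


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with square kernel/stride/padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            np.zeros((out_channels, in_channels, kernel_size, kernel_size),
                     dtype=np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32),
                              is_bias=True)
        self._col: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (N, C, Ho, Wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                   ).reshape(n * ho * wo, c * k * k)
        self._col = col
        self._xshape = (n, c, h, w, ho, wo)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = col @ wmat.T + self.bias.data
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo = self._xshape
        k, s, p = self.kernel_size, self.stride, self.padding
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)
                                    ).reshape(n * ho * wo, self.out_channels)
        self.weight.grad += (gmat.T @ self._col).reshape(self.weight.data.shape)
        self.bias.grad += gmat.sum(axis=0)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        dcol = (gmat @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        # scatter-add each kernel offset back onto the padded grid
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Layer):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (n, c, h, w, ho, wo, idx)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo, idx = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        ni, ci, ii, ji = np.indices((n, c, ho, wo), sparse=False)
        rows = ii * s + idx // k
        cols = ji * s + idx % k
        np.add.at(dxp, (ni, ci, rows, cols), grad)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class PReLU(Layer):
    """Parametric rectifier with a scheduled (not gradient-trained)
    negative-part slope shared across the layer."""

    def __init__(self, slope: float = 0.9):
        self.slope = float(slope)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, np.float32(self.slope) * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, np.float32(self.slope) * grad)


class LocalResponseNorm(Layer):
    """Cross-channel LRN: ``b = a / (k + (alpha/n) * S)^beta`` with S the
    windowed sum of squared activations over ``n//2`` channels each side
    (truncated at the borders)."""

    def __init__(self, k: float, n: int, alpha: float, beta: float):
        if n < 1 or beta <= 0:
            raise ValueError("need n >= 1 and beta > 0")
        self.k = float(k)
        self.n = int(n)
        self.alpha = float(alpha)
        self.beta = float(beta)
        self._cache: tuple | None = None

    def _window_sum(self, x: np.ndarray) -> np.ndarray:
        half = self.n // 2
        c = x.shape[1]
        cs = np.concatenate(
            [np.zeros_like(x[:, :1]), np.cumsum(x, axis=1)], axis=1)
        lo = np.maximum(np.arange(c) - half, 0)
        hi = np.minimum(np.arange(c) + half + 1, c)
        return cs[:, hi] - cs[:, lo]

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self._window_sum(x.astype(np.float32) ** 2)
        d = self.k + (self.alpha / self.n) * s
        dpow = d ** (-self.beta)
        self._cache = (x, d, dpow)
        return x * dpow

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, d, dpow = self._cache
        t = grad * x * dpow / d                  # g * a * d^-(beta+1)
        return grad * dpow - (2.0 * self.alpha * self.beta / self.n) * x * \
            self._window_sum(t)


class PixelShuffle(Layer):
    """Sub-pixel rearrangement: (N, C*r^2, H, W) -> (N, C, r*H, r*W).

    Each group of r^2 channels redistributes into an r x r spatial block;
    the element multiset is preserved exactly.
    """

    def __init__(self, upscale: int = 2):
        self.r = int(upscale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = self.r
        if c % (r * r):
            raise ValueError("channels must be divisible by the square of the factor")
        co = c // (r * r)
        y = x.reshape(n, co, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y.reshape(n, co, h * r, w * r))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.inverse(grad)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        n, co, hr, wr = y.shape
        r = self.r
        h, w = hr // r, wr // r
        x = y.reshape(n, co, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(x.reshape(n, co * r * r, h, w))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int):
        self.weight = Parameter(np.zeros((out_features, in_features),
                                         dtype=np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32),
                              is_bias=True)
        self._x: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def prelu_layers(self) -> list[PReLU]:
        return [l for l in self.layers if isinstance(l, PReLU)]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean element-wise binary cross-entropy on logits; returns (loss, dlogits)."""
    t = targets.astype(np.float32)
    # stable: log(1+exp(-|x|)) + max(x,0) - x*t
    loss = np.mean(np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0)
                   - logits * t)
    dlogits = (sigmoid(logits) - t) / logits.size
    return float(loss), dlogits.astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class (or C-class) cross-entropy; labels are integer indices."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    """SGD with (rampable) momentum and decoupled-into-gradient weight decay.

    Biases are excluded from weight decay.  ``momentum`` can be changed
    between steps (the training recipe ramps it over the first epochs).
    """

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0005):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay and not p.is_bias:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
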