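"""Minimal NHWC layer zoo with hand-written backprop (float32).

Implemented exactly as needed by the driver classifier: valid-padding 3x3
convolutions, 2x2 max-pooling (truncating odd remainders, as Keras does),
dense layers, inverted dropout and a softmax head.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> List[np.ndarray]:
        return []

    def gradients(self) -> List[np.ndarray]:
        return []


class Conv2D(Layer):
    """3x3 (configurable) valid convolution, stride 1, He-initialized."""

    trainable = True

    def __init__(self, in_channels: int, filters: int, ksize: int = 3, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * in_channels
        self.w = (rng.standard_normal((ksize, ksize, in_channels, filters)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.ksize = ksize
        self._cols = None
        self._xshape = None

    def forward(self, x, train=False):
        k = self.ksize
        b, h, w, c = x.shape
        oh, ow = h - k + 1, w - k + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for {k}x{k} convolution")
        win = sliding_window_view(x, (k, k), axis=(1, 2))        # (B, oh, ow, C, k, k)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * oh * ow, k * k * c)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        # column-major weight copy: measurably faster sgemm for these shapes
        out = cols @ np.asfortranarray(self.w.reshape(-1, self.w.shape[-1])) + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(b, oh, ow, -1)

    need_input_grad = True  # cleared for the first layer of a network

    def backward(self, dy):
        k = self.ksize
        b, oh, ow, f = dy.shape
        dy_flat = dy.reshape(-1, f).astype(np.float32)
        self.dw = (dy_flat.T @ self._cols).T.reshape(self.w.shape)
        self.db = dy_flat.sum(axis=0)
        self._cols = None
        if not self.need_input_grad:
            return None
        dcols = (dy_flat @ self.w.reshape(-1, f).T).reshape(b, oh, ow, k, k, -1)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * (self._y > 0)


class MaxPool2(Layer):
    """Non-overlapping 2x2 max pooling; trailing odd rows/cols are dropped."""

    def forward(self, x, train=False):
        b, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for 2x2 pooling")
        x0 = x[:, 0:2 * oh:2, :2 * ow, :]
        x1 = x[:, 1:2 * oh:2, :2 * ow, :]
        rowmax = np.maximum(x0, x1)
        c0 = rowmax[:, :, 0::2, :]
        c1 = rowmax[:, :, 1::2, :]
        out = np.maximum(c0, c1)
        if train:
            # winner masks (ties -> first cell), enough to route gradients
            self._row_w = x0 >= x1
            self._col_w = c0 >= c1
            self._xshape = x.shape
        return out

    def backward(self, dy):
        b, h, w, c = self._xshape
        oh, ow = h // 2, w // 2
        drow = np.zeros((b, oh, 2 * ow, c), dtype=np.float32)
        drow[:, :, 0::2, :] = dy * self._col_w
        drow[:, :, 1::2, :] = dy * ~self._col_w
        dx = np.zeros(self._xshape, dtype=np.float32)
        dx[:, 0:2 * oh:2, :2 * ow, :] = drow * self._row_w
        dx[:, 1:2 * oh:2, :2 * ow, :] = drow * ~self._row_w
        self._row_w = self._col_w = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.w = (rng.standard_normal((in_features, out_features)) * np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dy):
        dy = dy.astype(np.float32)
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class Dropout(Layer):
    """Inverted dropout; active only when train=True."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Softmax(Layer):
    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, dy):  # pragma: no cover - training bypasses the softmax
        raise RuntimeError("backprop through Softmax is folded into the loss")


class Sequential:
    """Layer stack whose last layer is the softmax head."""

    def __init__(self, layers: List[Layer]):
        if not isinstance(layers[-1], Softmax):
            raise ValueError("last layer must be Softmax")
        self.layers = layers
        if isinstance(layers[0], Conv2D):
            layers[0].need_input_grad = False  # nothing upstream to update

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x, train=train)
        return x

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers[:-1]):
            dy = layer.backward(dy)

    def parameters(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def set_parameters(self, params: List[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(params):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(own, params):
            if dst.shape != src.shape:
                raise ValueError("parameter shape mismatch")
            dst[...] = src


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
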