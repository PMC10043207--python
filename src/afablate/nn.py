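"""Minimal CNN engine in numpy: forward, backprop and Adam.

Supports exactly what the outcome classifier and its attribution methods
need - stride-1 same-padded convolutions, ReLU, 2x2 max pooling, linear
layers, inverted dropout and a sigmoid head - with gradients available both
for the weights (training) and for intermediate activations (GradCAM).
Deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 convolution with same padding, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng):
        super().__init__()
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _windows(self, x):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k)
        return sliding_window_view(xp, (self.k, self.k), axis=(2, 3))

    def forward(self, x, train, rng):
        self._x = x
        win = self._windows(x)
        N, C, H, W, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * self.k * self.k)
        self._cols, self._shape = cols, (N, H, W)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(N, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        N, H, W = self._shape
        O = self.W.shape[0]
        dyc = dy.transpose(0, 2, 3, 1).reshape(N * H * W, O)
        self.grads[0][...] = (dyc.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = dyc.sum(axis=0)
        # dx: correlate dy with the flipped kernel
        Wflip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, O * self.k * self.k)
        dx = cols @ Wflip.reshape(Wflip.shape[0], -1).T
        return dx.reshape(N, H, W, -1).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even inputs only)."""

    def forward(self, x, train, rng):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(N, C, H // 2, W // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        N, C, Hh, Wh = dy.shape
        flat = np.zeros((N, C, Hh, Wh, 4))
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        x = flat.reshape(N, C, Hh, Wh, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return x.reshape(self._inshape)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train, rng):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy, stop_at: int = 0):
        """Backpropagate ``dy`` through layers [stop_at:]; returns the
        gradient flowing into layer ``stop_at``."""
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = state[i]
                i += 1


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
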