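"""Minimal seeded neural-network core (numpy).

Just enough machinery for the gait models: 3x3 same-padding convolution
via im2col, 2x2 max pooling, dense layers, ReLU, softmax cross-entropy,
mean-squared error and Adam.  Everything is float32, batch-first
(N, C, H, W), and deterministic given the construction seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_grad",
    "mse_grad",
]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero ('same') padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = _he_init(rng, (c_out, c_in * 9), c_in * 9)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # x: (N, C, H, W) zero-padded by 1 -> (N, H, W, C*9)
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h, w, c * 9
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        w, b = self.params
        y = self._cols @ w.T + b  # (N, H, W, C_out)
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        n, _, h, wd = self._x_shape
        dyt = dy.transpose(0, 2, 3, 1)  # (N, H, W, C_out)
        self.grads[0][...] = np.tensordot(dyt, self._cols, axes=([0, 1, 2], [0, 1, 2]))
        self.grads[1][...] = dyt.sum(axis=(0, 1, 2))
        # dx by full correlation of dy with the flipped kernel
        wk = w.reshape(self.c_out, self.c_in, 3, 3)
        wflip = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out,3,3)
        cols_dy = self._im2col(dy)  # (N, H, W, C_out*9)
        dx = cols_dy @ wflip.reshape(self.c_in, self.c_out * 9).T
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr.reshape(n, c, h, w))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        w = _he_init(rng, (d_in, d_out), d_in)
        b = np.zeros(d_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def mse_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float((diff**2).mean())
    grad = (2.0 * diff / diff.size).astype(np.float32)
    return loss, grad
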