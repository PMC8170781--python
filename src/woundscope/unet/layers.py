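"""Minimal CNN layers (forward + backward) in numpy, NHWC layout.

Only what a small U-net needs: 'same' 3x3 / 1x1 convolutions, ReLU, 2x2
max pooling, 2x2 stride-2 transposed convolution and inverted dropout.
Convolutions are evaluated as k*k shifted (N*H*W, C_in) @ (C_in, C_out)
matrix products, which keeps everything in BLAS without materialising an
im2col tensor.  Each layer caches what its backward pass needs;
parameters and gradients are exposed as flat lists for the optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv", "ReLU", "MaxPool2", "UpConv2", "Dropout", "Adam"]


class Conv:
    """k x k convolution with zero 'same' padding, He-initialised.

    Weights have shape (k, k, c_in, c_out); input/output are (N, H, W, C).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        flat = None
        for ki in range(k):
            for kj in range(k):
                sl = np.ascontiguousarray(xp[:, ki : ki + h, kj : kj + w, :]).reshape(n * h * w, c)
                term = sl @ self.W[ki, kj]
                flat = term if flat is None else flat + term
        flat += self.b
        return flat.reshape(n, h, w, self.c_out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, _ = gy.shape
        k, p = self.k, self.k // 2
        g = gy.reshape(n * h * w, self.c_out)
        self.db[...] = g.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                sl = np.ascontiguousarray(xp[:, ki : ki + h, kj : kj + w, :]).reshape(n * h * w, self.c_in)
                self.dW[ki, kj] = sl.T @ g
                dxp[:, ki : ki + h, kj : kj + w, :] += (g @ self.W[ki, kj].T).reshape(n, h, w, self.c_in)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2:
    """2x2 max pooling; requires even spatial dimensions."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=gy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        return dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


class UpConv2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), (2, 2, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        self._x = x
        y = np.empty((n, 2 * h, 2 * w, self.c_out), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                y[:, i::2, j::2, :] = x @ self.W[i, j]
        return y + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        flat_x = x.reshape(-1, x.shape[-1])
        for i in range(2):
            for j in range(2):
                g = np.ascontiguousarray(gy[:, i::2, j::2, :]).reshape(-1, self.c_out)
                self.dW[i, j] = flat_x.T @ g
                dx += (g @ self.W[i, j].T).reshape(x.shape)
        self.db[...] = gy.sum(axis=(0, 1, 2))
        self._x = None
        return dx


class Dropout:
    """Inverted dropout; identity in eval mode."""

    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Adam:
    """Adam with a per-call learning rate (the schedule lives outside)."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
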