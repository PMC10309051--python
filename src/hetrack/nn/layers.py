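"""Forward/backward layer implementations (NHWC, float32)."""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense"]


class Layer:
    """Base layer: trainable parameters live in ``params``/``grads``."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, same padding.

    Implemented as a sum of k*k shifted matrix products rather than im2col:
    the k*k loop keeps memory at one activation map while still spending
    nearly all time in BLAS.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel side must be odd for same padding")
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        w = rng.normal(0.0, scale, (kernel, kernel, in_channels, out_channels))
        self.w = w.astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        n, h, w, cin = x.shape
        xp = np.pad(x.astype(self.w.dtype, copy=False),
                    ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.b.shape[0])).copy()
        flat = out.reshape(-1, self.b.shape[0])
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + h, j:j + w, :].reshape(-1, cin)
                flat += xs @ self.w[i, j]
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = self._xp
        assert xp is not None
        n, hp, wp, cin = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        cout = self.b.shape[0]
        dflat = dout.reshape(-1, cout)
        dw = self.grads[0]
        dw[...] = 0.0
        self.grads[1][...] = dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i:i + h, j:j + w, :].reshape(-1, cin)
                dw[i, j] = xs.T @ dflat
                dxp[:, i:i + h, j:j + w, :] += (dflat @ self.w[i, j].T).reshape(n, h, w, cin)
        return dxp[:, p:hp - p, p:wp - p, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(dout.dtype)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/column is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :h2 * 2, :w2 * 2, :]
        windows = (
            xc.reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, 4)
        )
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        scattered = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(scattered, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :h2 * 2, :w2 * 2, :] = (
            scattered.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.w = rng.normal(0.0, scale, (in_features, out_features)).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(self.w.dtype, copy=False)
        return self._x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T
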