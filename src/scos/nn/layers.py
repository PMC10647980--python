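"""Minimal NumPy layers with explicit forward/backward passes.

All layers operate on arrays of shape (N, C, H, W) in float32. Each layer
caches what its backward pass needs during forward; calling ``backward``
before ``forward`` is a usage error. The ReLU backward supports the guided
variant (gradients rectified at every unit) used for saliency analysis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: layers expose ``params``/``grads`` dicts keyed by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2D(Layer):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("Conv2D supports odd kernels only")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2
        self.params["W"] = he_uniform(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._col = None
        self._xshape = None

    def forward(self, x):
        n, c, h, w = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        view = sliding_window_view(xp, (k, k), axis=(2, 3))
        col = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
        wmat = self.params["W"].reshape(self.cout, -1)
        y = col @ wmat.T + self.params["b"]
        self._col, self._xshape = col, x.shape
        return np.ascontiguousarray(y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, c, h, w = self._xshape
        p, k = self.pad, self.k
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads["W"] += (dy_flat.T @ self._col).reshape(self.params["W"].shape)
        self.grads["b"] += dy_flat.sum(axis=0)
        # dx is the correlation of dy with the flipped, transposed kernel —
        # another same-padded convolution, reusing the fast forward path
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dyp = np.pad(dy.reshape(n, self.cout, h, w), ((0, 0), (0, 0), (p, p), (p, p)))
        view = sliding_window_view(dyp, (k, k), axis=(2, 3))
        dycol = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.cout * k * k)
        dx = dycol @ w_flip.reshape(c, -1).T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy, guided: bool = False):
        dx = np.where(self._mask, dy, 0)
        if guided:
            dx = np.where(dx > 0, dx, 0)
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties route gradient to the first maximum."""

    def __init__(self):
        super().__init__()
        self._idx = None
        self._xshape = None

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._idx = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._xshape
        ho, wo = h // 2, w // 2
        dxr = np.zeros((n, c, ho, wo, 4), dtype=np.asarray(dy).dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact upsampling by 2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.params["W"] = he_uniform(rng, (cin, cout, 2, 2), fan_in=cin)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._x = None

    def forward(self, x):
        n, c, h, w = x.shape
        y = np.empty((n, self.cout, 2 * h, 2 * w),
                     dtype=np.result_type(x.dtype, self.params["W"].dtype))
        for i in range(2):
            for j in range(2):
                y[:, :, i::2, j::2] = np.einsum(
                    "nchw,co->nohw", x, self.params["W"][:, :, i, j], optimize=True
                )
        y += self.params["b"][None, :, None, None]
        self._x = x
        return y

    def backward(self, dy):
        dx = np.zeros_like(self._x)
        for i in range(2):
            for j in range(2):
                sub = dy[:, :, i::2, j::2]
                self.grads["W"][:, :, i, j] += np.einsum(
                    "nchw,nohw->co", self._x, sub, optimize=True
                )
                dx += np.einsum("nohw,co->nchw", sub, self.params["W"][:, :, i, j], optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        return dx


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x):
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy
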