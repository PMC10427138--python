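"""Minimal CNN building blocks in numpy with explicit backpropagation.

Activations use NHWC layout (batch, height, width, channels), float32.
Convolutions are computed as im2col + BLAS matmul; the gradient with
respect to the input is itself a same-padded convolution with the flipped,
channel-transposed kernel, so forward and backward share one fast
primitive.  Everything is deterministic given the init seed: no threading
or atomics enter the computation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2x2", "UpsampleNearest2x", "sigmoid", "Adam"]


def _he_init(rng: np.random.Generator, k: int, cin: int, cout: int) -> np.ndarray:
    sd = np.sqrt(2.0 / (k * k * cin))
    return rng.normal(0.0, sd, size=(k, k, cin, cout)).astype(np.float32)


def _conv_same(x: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded stride-1 correlation of NHWC x with (k,k,Cin,Cout) kernel.

    Returns (output, im2col matrix) — the column matrix is reused for the
    weight gradient.
    """
    k = W.shape[0]
    pad = (k - 1) // 2
    n, h, w, cin = x.shape
    if k == 1:
        cols = x.reshape(n * h * w, cin)
    else:
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n,h,w,cin,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * cin
        )
    out = cols @ W.reshape(-1, W.shape[-1])
    return out.reshape(n, h, w, W.shape[-1]), cols


class Conv2d:
    """k x k same-padded convolution with bias; k must be odd."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.W = _he_init(rng, k, cin, cout)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = k, cin, cout
        self._cols: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._cols = _conv_same(x, self.W)
        return out + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, cout = dout.shape
        dflat = dout.reshape(n * h * w, cout)
        self.dW = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        if self.k == 1:
            dx = dflat @ self.W.reshape(self.cin, self.cout).T
            return dx.reshape(n, h, w, self.cin)
        # dL/dx = dout (*) flip(W) with swapped in/out channels
        W_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,cout,cin)
        dx, _ = _conv_same(dout, np.ascontiguousarray(W_flip))
        return dx

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ReLU:
    """Leaky rectifier; the small negative slope keeps gradient flowing
    through units that would otherwise die (no normalization layers exist
    in this network to rescue them)."""

    slope = np.float32(0.1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout).astype(np.float32, copy=False)


class MaxPool2x2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even dims, got {h}x{w}")
        self._in_shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class UpsampleNearest2x:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        return dout.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adaptive-moment optimizer over a model's (param, grad) pairs."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[tuple[str, np.ndarray, np.ndarray]], lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (_, p, g) in enumerate(params):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
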