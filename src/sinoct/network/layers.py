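"""NumPy layers with explicit forward/backward passes.

Feature maps are ``(height, width, channels)`` float64 arrays.  Every layer
caches what its backward pass needs; a layer instance therefore belongs to a
single position in a network and handles one example at a time (the training
regime here is batch size 1).

Spatial size rules follow the "SAME" convention: stride-1 convolutions
preserve the spatial size, stride-2 operations map ``n -> ceil(n / 2)`` with
zero padding split towards bottom/right.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Add",
    "ChannelNorm",
    "Conv2D",
    "ConvTranspose2D",
    "GlobalNorm",
    "MaxPool2x2",
    "MeanPool2x2",
    "ReLU",
    "downsample",
]


def _same_pads(n: int, stride: int, kernel: int) -> Tuple[int, int]:
    out = math.ceil(n / stride)
    total = max((out - 1) * stride + kernel - n, 0)
    lead = total // 2
    return lead, total - lead


class Layer:
    """Base: layers expose flat parameter/gradient lists for the optimizer."""

    @property
    def params(self) -> List[np.ndarray]:
        return []

    @property
    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution, SAME padding, arbitrary square kernel and stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1):
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.stride = stride
        self.w = np.zeros((kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def fan_in(self) -> int:
        return self.kernel * self.kernel * self.c_in

    @property
    def fan_out(self) -> int:
        return self.kernel * self.kernel * self.c_out

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, _ = x.shape
        s, k = self.stride, self.kernel
        oh, ow = math.ceil(h / s), math.ceil(w / s)
        pt, pb = _same_pads(h, s, k)
        pl, pr = _same_pads(w, s, k)
        xp = np.pad(x, ((pt, pb), (pl, pr), (0, 0)))
        self._xp = xp
        self._in_shape = (h, w)
        self._pads = (pt, pl)
        out = np.broadcast_to(self.b, (oh, ow, self.c_out)).copy()
        for ki in range(k):
            for kj in range(k):
                xs = xp[ki::s, kj::s][:oh, :ow]
                out += np.tensordot(xs, self.w[ki, kj], axes=([2], [0]))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, k = self.stride, self.kernel
        oh, ow, _ = dy.shape
        xp = self._xp
        h, w = self._in_shape
        pt, pl = self._pads
        self.db[...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[ki::s, kj::s][:oh, :ow]
                self.dw[ki, kj] = np.tensordot(xs, dy, axes=([0, 1], [0, 1]))
                dxp[ki : ki + s * oh : s, kj : kj + s * ow : s] += np.tensordot(
                    dy, self.w[ki, kj], axes=([2], [1])
                )
        return dxp[pt : pt + h, pl : pl + w]


class ConvTranspose2D(Layer):
    """2x up-sampling transposed convolution (adjoint of a SAME stride-2 conv).

    The output spatial size is supplied at call time so odd encoder sizes are
    restored exactly (e.g. 183 -> 92 -> 183).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 2):
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.stride = stride
        self.w = np.zeros((kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def fan_in(self) -> int:
        return self.kernel * self.kernel * self.c_in

    @property
    def fan_out(self) -> int:
        return self.kernel * self.kernel * self.c_out

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, out_hw: Tuple[int, int]) -> np.ndarray:
        h, w, _ = x.shape
        th, tw = out_hw
        s, k = self.stride, self.kernel
        if math.ceil(th / s) != h or math.ceil(tw / s) != w:
            raise ValueError(
                f"transposed conv cannot map {x.shape[:2]} to {out_hw} at stride {s}"
            )
        pt, pb = _same_pads(th, s, k)
        pl, pr = _same_pads(tw, s, k)
        ypad = np.zeros((th + pt + pb, tw + pl + pr, self.c_out))
        for ki in range(k):
            for kj in range(k):
                ypad[ki : ki + s * h : s, kj : kj + s * w : s] += np.tensordot(
                    x, self.w[ki, kj], axes=([2], [0])
                )
        self._x = x
        self._pads = (pt, pb, pl, pr)
        self._out_hw = (th, tw)
        return ypad[pt : pt + th, pl : pl + tw] + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, k = self.stride, self.kernel
        x = self._x
        h, w, _ = x.shape
        pt, pb, pl, pr = self._pads
        self.db[...] = dy.sum(axis=(0, 1))
        dypad = np.pad(dy, ((pt, pb), (pl, pr), (0, 0)))
        dx = np.zeros_like(x)
        for ki in range(k):
            for kj in range(k):
                ys = dypad[ki : ki + s * h : s, kj : kj + s * w : s]
                self.dw[ki, kj] = np.tensordot(x, ys, axes=([0, 1], [0, 1]))
                dx += np.tensordot(ys, self.w[ki, kj], axes=([2], [1]))
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class ChannelNorm(Layer):
    """Per-channel feature-map standardization with learned scale and shift.

    This is batch normalization in the batch-size-1 regime, where the batch
    statistics degenerate to the statistics of the single feature map; the
    layer is then identical in training and inference, which keeps the whole
    network deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - xhat * (dxhat * xhat).mean(axis=(0, 1))
        ) / self._std


class GlobalNorm(Layer):
    """Whole-map standardization (zero mean, unit population std), no
    learnable parameters; used as the network's final layer."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean()
        self._std = math.sqrt(x.var() + self.eps)
        self._y = (x - mu) / self._std
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return (dy - dy.mean() - y * (dy * y).mean()) / self._std


class Add(Layer):
    """Residual addition of a stored reference map."""

    def forward(self, x: np.ndarray, residual: np.ndarray) -> np.ndarray:
        return x + residual

    def backward(self, dy: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return dy, dy


def _pool_windows(x: np.ndarray, pad_value: float) -> Tuple[np.ndarray, ...]:
    h, w = x.shape[:2]
    ph, pw = h % 2, w % 2
    xp = np.pad(x, ((0, ph), (0, pw)) + ((0, 0),) * (x.ndim - 2),
                constant_values=pad_value)
    return xp[0::2, 0::2], xp[0::2, 1::2], xp[1::2, 0::2], xp[1::2, 1::2]


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling; odd sizes ceil-padded."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        wins = np.stack(_pool_windows(x, -np.inf))
        self._argmax = wins.argmax(axis=0)
        self._in_shape = x.shape
        return np.take_along_axis(wins, self._argmax[None], axis=0)[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._in_shape[:2]
        dxp = np.zeros((h + h % 2, w + w % 2) + self._in_shape[2:])
        slices = ((0, 0), (0, 1), (1, 0), (1, 1))
        for s, (di, dj) in enumerate(slices):
            sel = self._argmax == s
            view = dxp[di::2, dj::2]
            view[sel] += dy[sel]
        return dxp[:h, :w]


class MeanPool2x2(Layer):
    """2x2, stride-2 mean pooling; zero-padded, fixed divisor 4 (so that a
    strided 2x2 convolution with all coefficients 1/4 matches it exactly)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        w00, w01, w10, w11 = _pool_windows(x, 0.0)
        return (w00 + w01 + w10 + w11) / 4.0

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._in_shape[:2]
        dxp = np.zeros((h + h % 2, w + w % 2) + self._in_shape[2:])
        q = dy / 4.0
        for di, dj in ((0, 0), (0, 1), (1, 0), (1, 1)):
            dxp[di::2, dj::2] += q
        return dxp[:h, :w]


def downsample(
    feature_map: np.ndarray,
    coefficients: Optional[Sequence[float]] = None,
    mode: str = "strided_conv",
) -> np.ndarray:
    """Reduce each spatial axis ``n -> ceil(n/2)`` with a 2x2, stride-2 window.

    ``strided_conv`` combines the window as ``C11*v11 + C12*v12 + C21*v21 +
    C22*v22`` with the supplied coefficients (per-channel, depthwise);
    ``max_pool`` / ``mean_pool`` apply the fixed reductions.
    """
    if mode == "strided_conv":
        if coefficients is None:
            raise ValueError("strided_conv mode requires 4 window coefficients")
        c11, c12, c21, c22 = (float(c) for c in coefficients)
        w00, w01, w10, w11 = _pool_windows(np.asarray(feature_map, float), 0.0)
        return c11 * w00 + c12 * w01 + c21 * w10 + c22 * w11
    if mode == "max_pool":
        return MaxPool2x2().forward(np.asarray(feature_map, float))
    if mode == "mean_pool":
        return MeanPool2x2().forward(np.asarray(feature_map, float))
    raise ValueError(f"unknown down-sampling mode {mode!r}")
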