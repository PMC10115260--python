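"""Minimal numpy CNN backend for 2-D semantic segmentation.

Implements exactly the pieces the disease-region segmenter needs — stride-1
'same' convolutions (im2col matmuls), batch normalisation, ReLU, 2x2 max
pooling, nearest-neighbour 2x upsampling with skip concatenation, a U-net
assembly, a numerically stable binary-cross-entropy-with-logits loss and the
Adam optimizer. Everything is deterministic given the RNG passed at
initialisation; all arrays are float64 (N, C, H, W).

The backward passes use the standard analytic gradients (convolution
gradients via correlation with spatially flipped, channel-swapped kernels;
the usual batch-norm chain rule). They are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "UNet2d",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross entropy on logits; returns (loss, dloss/dlogits)."""
    z, y = logits, targets
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad


def _corr2d(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """'Same' cross-correlation of x (N,C,H,W) with w (O,C,k,k), odd k.

    Returns (output (N,O,H,W), x_col (N*H*W, C*k*k)) — the im2col matrix is
    reused for the weight gradient.
    """
    n, c, h, wd = x.shape
    k = w.shape[2]
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    x_col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * k * k)
    out = x_col @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, h, wd, w.shape[0]).transpose(0, 3, 1, 2), x_col


class Conv2d:
    """Stride-1 'same' convolution with bias; odd kernel size."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(1.0 / fan_in)  # Kaiming-uniform style
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in, kernel, kernel))
        self.b = rng.uniform(-bound, bound, size=c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x_col = None
        self._x_shape = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out, x_col = _corr2d(x, self.w)
        if train:
            self._x_col = x_col
            self._x_shape = x.shape
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, h, wd = dout.shape
        dout_flat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, c_out)
        self.dw[...] = (dout_flat.T @ self._x_col).reshape(self.w.shape)
        self.db[...] = dout_flat.sum(axis=0)
        w_flip = self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        dx, _ = _corr2d(dout, np.ascontiguousarray(w_flip))
        self._x_col = None
        return dx


class BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (x_hat, inv_std)
        return self.gamma[None, :, None, None] * x_hat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * x_hat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        term = (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - x_hat * (dxhat * x_hat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self._cache = None
        return inv_std[None, :, None, None] / m * term


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pooling needs even spatial dims"
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._argmax = None
        return dx


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _DoubleConv:
    """(conv -> batchnorm -> ReLU) x 2."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.layers = [
            Conv2d(c_in, c_out, kernel, rng),
            BatchNorm2d(c_out),
            ReLU(),
            Conv2d(c_out, c_out, kernel, rng),
            BatchNorm2d(c_out),
            ReLU(),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet2d:
    """2-D U-net: encoder/decoder with skip concatenation, logits output.

    ``levels`` counts resolution levels (all feature maps between two
    pooling or two upsampling operations); channel width doubles per level
    from ``base_channels``. Spatial dims must be divisible by
    ``2 ** (levels - 1)``.
    """

    def __init__(self, levels: int, kernel: int, base_channels: int, seed: int):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        rng = np.random.default_rng(seed)
        self.levels = levels
        channels = [base_channels * 2**l for l in range(levels)]
        self.enc = []
        c_in = 1
        for l in range(levels):
            self.enc.append(_DoubleConv(c_in, channels[l], kernel, rng))
            c_in = channels[l]
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.ups = [Upsample2() for _ in range(levels - 1)]
        self.dec = []
        for l in range(levels - 2, -1, -1):
            self.dec.append(_DoubleConv(channels[l + 1] + channels[l], channels[l], kernel, rng))
        self.head = Conv2d(channels[0], 1, 1, rng)
        self._skip_channels = channels

    def params(self):
        out = []
        for block in [*self.enc, *self.dec, self.head]:
            out.extend(block.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for l in range(self.levels):
            x = self.enc[l].forward(x, train)
            if l < self.levels - 1:
                skips.append(x)
                x = self.pools[l].forward(x, train)
        self._skip_shapes = [s.shape for s in skips]
        for i, l in enumerate(range(self.levels - 2, -1, -1)):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([x, skips[l]], axis=1)
            x = self.dec[i].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dout: np.ndarray) -> None:
        dout = self.head.backward(dout)
        dskips = [None] * (self.levels - 1)
        for i in range(len(self.dec) - 1, -1, -1):
            l = self.levels - 2 - i
            d = self.dec[i].backward(dout)
            c_up = d.shape[1] - self._skip_shapes[l][1]
            dup, dskip = d[:, :c_up], d[:, c_up:]
            dskips[l] = dskip
            dout = self.ups[i].backward(dup)
        for l in range(self.levels - 1, -1, -1):
            if l < self.levels - 1:
                dout = self.pools[l].backward(dout)
                dout = dout + dskips[l]
            dout = self.enc[l].backward(dout)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities in eval mode (running BN stats)."""
        return sigmoid(self.forward(x, train=False))

    def _layers(self):
        out = []
        for block in [*self.enc, *self.dec]:
            out.extend(block.layers)
        out.append(self.head)
        return out

    def get_state(self) -> list[np.ndarray]:
        """All weights plus batch-norm running statistics, in a fixed order."""
        arrays = []
        for layer in self._layers():
            if isinstance(layer, Conv2d):
                arrays += [layer.w, layer.b]
            elif isinstance(layer, BatchNorm2d):
                arrays += [layer.gamma, layer.beta, layer.running_mean, layer.running_var]
        return arrays

    def set_state(self, arrays) -> None:
        it = iter(arrays)
        for layer in self._layers():
            if isinstance(layer, Conv2d):
                layer.w[...] = next(it)
                layer.b[...] = next(it)
            elif isinstance(layer, BatchNorm2d):
                layer.gamma[...] = next(it)
                layer.beta[...] = next(it)
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs, updated in place
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
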