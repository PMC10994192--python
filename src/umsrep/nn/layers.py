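"""Minimal CNN layer zoo with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
exposes trainable arrays through ``params`` (gradients accumulate into
``grads`` with matching keys).  Convolutions use TensorFlow-style ``same``
padding so that stride-2 encoders halve the spatial size exactly and
stride-1 dilated stacks preserve it.  All arithmetic is float32 by default;
``Sequential.astype`` promotes a network to float64 when high-precision
gradient checks are wanted.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: stateless layers need only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def initialize(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        return None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def astype(self, dtype) -> None:
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)


def _same_pad(size: int, kernel_eff: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel_eff - size, 0)
    return total // 2, total - total // 2


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride, dilation, same/valid padding.

    Weight layout: (out_channels, in_channels, kh, kw).  Initialization is
    fan-in-scaled uniform (LeCun): U(-sqrt(3/fan_in), +sqrt(3/fan_in)).
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, dilation=1, padding="same"):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.dilation = int(kernel), int(stride), int(dilation)
        self.padding = padding
        self.params = {
            "W": np.zeros((self.c_out, self.c_in, self.kernel, self.kernel), DTYPE),
            "b": np.zeros(self.c_out, DTYPE),
        }

    def initialize(self, rng):
        fan_in = self.c_in * self.kernel * self.kernel
        limit = np.sqrt(3.0 / fan_in)
        w = rng.uniform(-limit, limit, self.params["W"].shape)
        self.params["W"] = w.astype(self.params["W"].dtype)
        self.params["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, training=False):
        W, b = self.params["W"], self.params["b"]
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"conv expected {self.c_in} channels, got {c}")
        ke = self.dilation * (self.kernel - 1) + 1
        if self.padding == "same":
            (pt, pb), (pl, pr) = _same_pad(h, ke, self.stride), _same_pad(w, ke, self.stride)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - ke) // self.stride + 1
        wo = (wp - ke) // self.stride + 1
        out = np.empty((n, ho, wo, self.c_out), dtype=x.dtype)
        out[:] = b.astype(x.dtype)
        for i in range(self.kernel):
            for j in range(self.kernel):
                xs = xp[:, :,
                        i * self.dilation: i * self.dilation + (ho - 1) * self.stride + 1: self.stride,
                        j * self.dilation: j * self.dilation + (wo - 1) * self.stride + 1: self.stride]
                out += np.tensordot(xs, W[:, :, i, j].astype(x.dtype), axes=([1], [1]))
        self._cache = (xp, (pt, pb, pl, pr), (n, c, h, w), (ho, wo))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gout):
        xp, (pt, pb, pl, pr), (n, c, h, w), (ho, wo) = self._cache
        W = self.params["W"]
        gt = np.ascontiguousarray(gout.transpose(0, 2, 3, 1))  # N,Ho,Wo,F
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for i in range(self.kernel):
            for j in range(self.kernel):
                sl_h = slice(i * self.dilation, i * self.dilation + (ho - 1) * self.stride + 1, self.stride)
                sl_w = slice(j * self.dilation, j * self.dilation + (wo - 1) * self.stride + 1, self.stride)
                xs = xp[:, :, sl_h, sl_w]
                dW[:, :, i, j] = np.tensordot(gt, xs, axes=([0, 1, 2], [0, 2, 3])).astype(W.dtype)
                dxp[:, :, sl_h, sl_w] += np.tensordot(gt, W[:, :, i, j].astype(gt.dtype),
                                                      axes=([3], [0])).transpose(0, 3, 1, 2)
        self.grads["W"] = dW
        self.grads["b"] = gout.sum(axis=(0, 2, 3)).astype(W.dtype)
        return dxp[:, :, pt:pt + h, pl:pl + w]


class BatchNorm(Layer):
    """Per-channel batch normalization; gamma/beta trainable, running stats not."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = int(channels)
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(self.channels, DTYPE), "beta": np.zeros(self.channels, DTYPE)}
        self.running_mean = np.zeros(self.channels, DTYPE)
        self.running_var = np.ones(self.channels, DTYPE)

    def astype(self, dtype):
        super().astype(dtype)
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)

    def forward(self, x, training=False):
        g = self.params["gamma"].reshape(1, -1, 1, 1)
        b = self.params["beta"].reshape(1, -1, 1, 1)
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).reshape(1, -1, 1, 1).astype(x.dtype)
        xhat = (x - mean.reshape(1, -1, 1, 1).astype(x.dtype)) / std
        self._cache = (xhat, std, training)
        return g.astype(x.dtype) * xhat + b.astype(x.dtype)

    def backward(self, gout):
        xhat, std, training = self._cache
        g = self.params["gamma"].reshape(1, -1, 1, 1).astype(gout.dtype)
        self.grads["gamma"] = (gout * xhat).sum(axis=(0, 2, 3)).astype(self.params["gamma"].dtype)
        self.grads["beta"] = gout.sum(axis=(0, 2, 3)).astype(self.params["beta"].dtype)
        if not training:
            return gout * g / std
        gs = gout * g
        mean_gs = gs.mean(axis=(0, 2, 3), keepdims=True)
        mean_gs_xhat = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gs - mean_gs - xhat * mean_gs_xhat) / std


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gout):
        return np.where(self._mask, gout, 0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class Softmax(Layer):
    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, gout):
        y = self._y
        return y * (gout - (gout * y).sum(axis=1, keepdims=True))


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAveragePool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    """Fully connected layer on (N, C_in) inputs."""

    def __init__(self, c_in, c_out):
        super().__init__()
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.params = {"W": np.zeros((self.c_in, self.c_out), DTYPE),
                       "b": np.zeros(self.c_out, DTYPE)}

    def initialize(self, rng):
        limit = np.sqrt(3.0 / self.c_in)
        self.params["W"] = rng.uniform(-limit, limit, (self.c_in, self.c_out)).astype(self.params["W"].dtype)
        self.params["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"].astype(x.dtype) + self.params["b"].astype(x.dtype)

    def backward(self, gout):
        self.grads["W"] = (self._x.T @ gout).astype(self.params["W"].dtype)
        self.grads["b"] = gout.sum(axis=0).astype(self.params["b"].dtype)
        return gout @ self.params["W"].T.astype(gout.dtype)


class Dropout(Layer):
    """Inverted dropout; identity outside training mode.

    Draws its masks from ``self.rng`` which the owning network seeds, so a
    fixed run seed reproduces the exact mask sequence.
    """

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask
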