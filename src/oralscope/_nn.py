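"""Minimal NumPy convolutional-network engine.

Implements exactly the pieces the classifier needs — 2-D convolution
(im2col + BLAS matmul), batch normalization, ReLU, and SGD with Nesterov
momentum and weight decay — with explicit forward/backward passes.  Shapes
follow the (N, C, H, W) convention; all math is float32.

This is intentionally a small engine, not a general autodiff framework: each
layer caches what its backward pass needs, and a network is a plain list of
layers applied in order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "Network", "SGD"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        #: whether weight decay applies (biases and BN affines are exempt)
        self.decay = decay


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    # (N*OH*OW, C*k*k)
    col = windows.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(col), (n, c, h, w, oh, ow, x.shape)


def _col2im(
    dcol: np.ndarray, meta: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    n, c, h, w, oh, ow, padded_shape = meta
    dx_pad = np.zeros(padded_shape, dtype=dcol.dtype)
    dwin = dcol.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx_pad[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += dwin[
                :, :, i, j
            ]
    if pad:
        return dx_pad[:, :, pad : pad + h, pad : pad + w]
    return dx_pad


class Conv2d:
    """k x k convolution with stride and symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.weight = Param(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Param(np.zeros(out_channels), decay=False)
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        col, meta = _im2col(x.astype(np.float32, copy=False), k, s, p)
        w2d = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = col @ w2d.T + self.bias.value
        n, _, _, _, oh, ow, _ = meta
        out = out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col, meta)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, meta = self._cache
        n, _, _, _, oh, ow, _ = meta
        cout = dout.shape[1]
        d2d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
        w2d = self.weight.value.reshape(cout, -1)
        self.weight.grad += (d2d.T @ col).reshape(self.weight.value.shape)
        self.bias.grad += d2d.sum(axis=0)
        dcol = d2d @ w2d
        return _col2im(dcol, meta, self.kernel_size, self.stride, self.padding)


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W).

    Training mode uses batch statistics and updates the running estimates;
    eval mode applies the running statistics, making the layer a fixed
    per-channel affine map.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, x.shape)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward through the batch statistics
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Network:
    """A plain sequence of layers with explicit forward/backward."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SGD:
    """Stochastic gradient descent with Nesterov momentum and weight decay.

    Matches the standard deep-learning formulation: ``v <- mu v + g`` and,
    with Nesterov, the applied gradient is ``g + mu v``.  Weight decay adds
    ``wd * w`` to the gradient of decaying parameters.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        nesterov: bool = True,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            update = g + self.momentum * v if self.nesterov else v
            p.value -= self.lr * update
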