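"""Minimal feed-forward layer library with explicit backpropagation.

Every layer is a :class:`Module` with ``forward(x, train)`` and
``backward(dout)``; ``forward`` caches whatever the matching ``backward``
needs, so calls must be strictly paired (forward, then backward) as they are
in an ordinary training loop.  All arithmetic is float32 numpy; convolutions
are lowered to matrix products through an im2col transform, which is the
standard CPU realisation and keeps the heavy lifting inside BLAS.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-style uniform init, U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    bound = math.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    """Base class: a parameterised, differentiable operator."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []

        def collect(v):
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in vars(self).values():
            collect(v)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            kaiming_uniform(rng, (out_features, in_features), in_features), "weight")
        self.bias = Parameter(np.zeros(out_features), "bias") if bias else None

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (C*k*k, N*oh*ow) patch matrix (copies).

    The channel-major layout lets forward and backward each run as one large
    2-D GEMM instead of a batch of small ones.
    """
    n, c = xp.shape[:2]
    cols = np.empty((c, k, k, n, oh, ow), dtype=xp.dtype)
    for ki in range(k):
        hi = ki + stride * oh
        for kj in range(k):
            wj = kj + stride * ow
            cols[:, ki, kj] = xp[:, :, ki:hi:stride, kj:wj:stride].transpose(1, 0, 2, 3)
    return cols.reshape(c * k * k, n * oh * ow)


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(c, k, k, n, oh, ow)
    for ki in range(k):
        hi = ki + stride * oh
        for kj in range(k):
            wj = kj + stride * ow
            dxp[:, :, ki:hi:stride, kj:wj:stride] += dcols[:, ki, kj].transpose(1, 0, 2, 3)
    return dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) with square kernel and zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size),
                            fan_in), "weight")
        self.bias = Parameter(np.zeros(out_channels), "bias") if bias else None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, oh, ow)
        self._cache = (x.shape, xp.shape, cols, oh, ow)
        wm = self.weight.value.reshape(self.out_channels, -1)
        y = (wm @ cols).reshape(self.out_channels, n, oh, ow).transpose(1, 0, 2, 3)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dout):
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        x_shape, xp_shape, cols, oh, ow = self._cache
        n = dout.shape[0]
        k, s, p = self.kernel_size, self.stride, self.padding
        dym = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(
            self.out_channels, n * oh * ow)
        self.weight.grad += (dym @ cols.T).reshape(self.weight.value.shape)
        wm = self.weight.value.reshape(self.out_channels, -1)
        dcols = wm.T @ dym
        dxp = _col2im(dcols, xp_shape, k, s, oh, ow)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    """Batch normalisation over (N,H,W) per channel, affine, running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features), "weight")
        self.bias = Parameter(np.zeros(num_features), "bias")
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train, x.shape)
        return self.weight.value[None, :, None, None] * xhat \
            + self.bias.value[None, :, None, None]

    def backward(self, dout):
        xhat, ivar, train, shape = self._cache
        self.weight.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        g = (self.weight.value * ivar)[None, :, None, None]
        if not train:
            return dout * g
        n, _, h, w = shape
        m = n * h * w
        sum_d = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dx = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        # batch-stats backward: remove the mean and the xhat-projection
        return g * (dout - sum_d / m - xhat * sum_dx / m)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Sigmoid(Module):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        windows = np.empty((k * k, n, c, oh, ow), dtype=x.dtype)
        for ki in range(k):
            hi = ki + s * oh
            for kj in range(k):
                wj = kj + s * ow
                windows[ki * k + kj] = xp[:, :, ki:hi:s, kj:wj:s]
        arg = windows.argmax(axis=0)
        self._cache = (arg, xp.shape, x.shape, oh, ow)
        return np.take_along_axis(windows, arg[None], axis=0)[0]

    def backward(self, dout):
        arg, xp_shape, x_shape, oh, ow = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for ki in range(k):
            hi = ki + s * oh
            for kj in range(k):
                wj = kj + s * ow
                sel = arg == (ki * k + kj)
                dxp[:, :, ki:hi:s, kj:wj:s] += np.where(sel, dout, 0)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool2d(Module):
    """N,C,H,W -> N,C mean over the spatial plane."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(dout.dtype)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x, train=False):
        for m in self.mods:
            x = m.forward(x, train=train)
        return x

    def backward(self, dout):
        for m in reversed(self.mods):
            dout = m.backward(dout)
        return dout


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean per-element binary cross-entropy on raw logits.

    Returns (loss, dlogits); numerically stable via softplus(z) - y*z.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    dz = ((p - y) / z.size).astype(DTYPE)
    return loss, dz


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Single-label softmax cross-entropy; targets are one-hot rows."""
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-(targets * logp).sum() / len(z))
    dz = ((np.exp(logp) - targets) / len(z)).astype(DTYPE)
    return loss, dz
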