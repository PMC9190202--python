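"""Core layers: convolution, batch normalization, ReLU, pooling, linear.

Initialisation follows He fan-in scaling for conv/linear weights; all layers
support an explicit backward pass used by the SGD trainer and by the
finite-difference gradient tests.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ShapeError
from .core import Module, Parameter
from .functional import col2im, conv_out_size, im2col


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if in_channels < 1 or out_channels < 1 or kernel_size < 1:
            raise ConfigurationError("conv dimensions must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def _params(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"conv expects [N,{self.in_channels},H,W], got {x.shape}"
            )
        n, _, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = conv_out_size(h, k, s, p), conv_out_size(w, k, s, p)
        if k == 1 and p == 0:
            # 1x1 convolution: strided subsample + channel matmul, no im2col
            xs = x[:, :, ::s, ::s] if s > 1 else x
            cols = np.ascontiguousarray(xs).reshape(n, self.in_channels, ho * wo)
        else:
            cols = im2col(x, k, s, p)  # [N, C*k*k, L]
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out = np.matmul(w2, cols)  # [N, Cout, L]
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if train:
            self._cache = (x.shape, cols)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n = grad_out.shape[0]
        k, s, p = self.kernel_size, self.stride, self.padding
        g2 = grad_out.reshape(n, self.out_channels, -1)  # [N, Cout, L]
        self.weight.grad += np.einsum("ncl,nkl->ck", g2, cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        w2 = self.weight.data.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, g2)  # [N, C*k*k, L]
        self._cache = None
        if k == 1 and p == 0:
            ho, wo = grad_out.shape[2], grad_out.shape[3]
            dx = np.zeros(x_shape, dtype=dcols.dtype)
            dx[:, :, ::s, ::s] = dcols.reshape(n, self.in_channels, ho, wo)
            return dx
        return col2im(dcols, x_shape, k, s, p)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Learnable scale/shift only; running mean/variance are buffers and are
    excluded from parameter counts. Normalization uses the biased batch
    variance, which is also what feeds the running average.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def _params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def _buffers(self):
        return ["running_mean", "running_var"]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ShapeError(f"batchnorm expects [N,{self.channels},H,W], got {x.shape}")
        if train:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            mean = x.sum(axis=(0, 2, 3)) / m
            # single-pass (biased) variance: E[x^2] - E[x]^2, allocation-free
            var = np.einsum("nchw,nchw->c", x, x) / m - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        # y = a*x + b with a, b folded per channel (one broadcast pass)
        a = self.gamma.data * invstd
        b = self.beta.data - mean * a
        out = x * a[None, :, None, None] + b[None, :, None, None]
        if train:
            self._cache = (x, mean, invstd)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, mean, invstd = self._cache
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = None
        n, _, h, w = grad_out.shape
        m = n * h * w
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        dxhat = grad_out * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out * self._mask
        self._mask = None
        return g


class GlobalAvgPool(Module):
    """[N,C,H,W] -> [N,C] spatial mean."""

    def __init__(self):
        self._hw = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        h, w = self._hw
        self._hw = None
        return np.broadcast_to(
            grad_out[:, :, None, None] / (h * w), grad_out.shape + (h, w)
        ).copy()


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(rng.normal(0.0, scale, (out_features, in_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))
        self._x = None

    def _params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ShapeError(f"linear expects [N,{self.in_features}], got {x.shape}")
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += grad_out.T @ x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data
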