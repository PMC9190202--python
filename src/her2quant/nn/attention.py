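"""Channel attention: gated channel transformation (GCT) and squeeze-and-excitation (SE).

GCT gates each channel with ``1 + tanh(gamma * s_hat + beta)`` where ``s_hat``
is the l2-normalised, ``alpha``-weighted l2 embedding of the channel. At its
initialisation (alpha=1, gamma=0, beta=0) the gate is exactly 1, so the module
is an identity map — training can only move away from a no-op.

SE squeezes with global average pooling, passes the channel statistics
through a biased bottleneck (reduction ``r``) with ReLU, and gates with a
sigmoid, so SE gates always lie strictly inside (0, 1).
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ShapeError
from .core import Module, Parameter


class GCT(Module):
    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        if channels < 1:
            raise ConfigurationError("GCT channels must be positive")
        if eps <= 0:
            raise ConfigurationError("GCT epsilon must be positive")
        self.channels = channels
        self.eps = eps
        self.alpha = Parameter(np.ones(channels, dtype=dtype))
        self.gamma = Parameter(np.zeros(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def _params(self):
        return [("alpha", self.alpha), ("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ShapeError(f"GCT expects [N,{self.channels},H,W], got {x.shape}")
        c = self.channels
        energy = np.einsum("nchw,nchw->nc", x, x)               # [N,C]
        n2 = np.sqrt(energy + self.eps)                         # l2 embedding
        s = self.alpha.data[None, :] * n2                       # [N,C]
        q = np.sqrt((s * s).sum(axis=1, keepdims=True) + self.eps)
        s_hat = s * np.sqrt(c) / q                              # channel normalisation
        u = self.gamma.data[None, :] * s_hat + self.beta.data[None, :]
        t = np.tanh(u)
        gate = 1.0 + t                                          # [N,C]
        out = x * gate[:, :, None, None]
        if train:
            self._cache = (x, n2, s, q, s_hat, t, gate)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, n2, s, q, s_hat, t, gate = self._cache
        self._cache = None
        c = self.channels
        dgate = (grad_out * x).sum(axis=(2, 3))                 # [N,C]
        dx = grad_out * gate[:, :, None, None]
        du = dgate * (1.0 - t * t)
        self.gamma.grad += (du * s_hat).sum(axis=0)
        self.beta.grad += du.sum(axis=0)
        ds_hat = du * self.gamma.data[None, :]
        # s_hat = sqrt(C) * s / q with q = sqrt(sum s^2 + eps)
        dot = (ds_hat * s).sum(axis=1, keepdims=True)
        ds = np.sqrt(c) * (ds_hat / q - s * dot / q**3)
        self.alpha.grad += (ds * n2).sum(axis=0)
        dn2 = ds * self.alpha.data[None, :]
        denergy = dn2 / (2.0 * n2)
        dx += 2.0 * x * denergy[:, :, None, None]
        return dx


class SEBlock(Module):
    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if channels < 1 or reduction < 1:
            raise ConfigurationError("SE channels and reduction must be positive")
        if channels % reduction:
            raise ConfigurationError(
                f"SE channels ({channels}) must be divisible by reduction ({reduction})"
            )
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        rng = rng or np.random.default_rng(0)
        self.w_reduce = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / channels), (hidden, channels)).astype(dtype)
        )
        self.b_reduce = Parameter(np.zeros(hidden, dtype=dtype))
        self.w_expand = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / hidden), (channels, hidden)).astype(dtype)
        )
        self.b_expand = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def _params(self):
        return [
            ("w_reduce", self.w_reduce),
            ("b_reduce", self.b_reduce),
            ("w_expand", self.w_expand),
            ("b_expand", self.b_expand),
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ShapeError(f"SE expects [N,{self.channels},H,W], got {x.shape}")
        z = x.mean(axis=(2, 3))                                  # squeeze [N,C]
        pre = z @ self.w_reduce.data.T + self.b_reduce.data
        h = np.maximum(pre, 0.0)
        a = h @ self.w_expand.data.T + self.b_expand.data
        gate = 1.0 / (1.0 + np.exp(-a))                          # [N,C] in (0,1)
        out = x * gate[:, :, None, None]
        if train:
            self._cache = (x, z, pre, h, gate)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, z, pre, h, gate = self._cache
        self._cache = None
        hw = x.shape[2] * x.shape[3]
        dgate = (grad_out * x).sum(axis=(2, 3))
        dx = grad_out * gate[:, :, None, None]
        da = dgate * gate * (1.0 - gate)
        self.w_expand.grad += da.T @ h
        self.b_expand.grad += da.sum(axis=0)
        dh = da @ self.w_expand.data
        dpre = dh * (pre > 0)
        self.w_reduce.grad += dpre.T @ z
        self.b_reduce.grad += dpre.sum(axis=0)
        dz = dpre @ self.w_reduce.data
        dx += dz[:, :, None, None] / hw
        return dx
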