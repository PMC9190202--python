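"""Tile-classifier architectures.

Three block families share one topology (five stages, stride 2 at each stage
start, global average pool, linear head):

* ``ECMBlock`` — training-time enhanced convolution module: parallel 3x3+BN,
  1x1+BN and (when stride is 1 and channels match) identity+BN branches,
  summed, then optional channel attention, then ReLU. Convolutions carry no
  bias because each branch's BN absorbs it.
* ``PlainBlock`` with bias — the deployment block: one 3x3 convolution with
  bias (the exact fusion of an ECM block), optional attention, ReLU.
* ``PlainBlock`` without bias/BN — the chain baseline used for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .errors import ShapeError
from .nn import GCT, BatchNorm2d, Conv2d, GlobalAvgPool, Linear, Module, ReLU, SEBlock


@dataclass
class ConvBNBranch:
    """One conv+BN branch in fusion form.

    ``bn_std`` is the standard deviation actually divided by at inference
    time, i.e. ``sqrt(running_var + eps)``; ``bias`` is None for the
    bias-free training convolutions.
    """

    kernel: np.ndarray  # [C_out, C_in, k, k]
    bias: np.ndarray | None
    bn_mean: np.ndarray
    bn_std: np.ndarray
    bn_scale: np.ndarray
    bn_shift: np.ndarray


@dataclass
class BNParams:
    """Stand-alone BN parameters (the identity branch of an ECM block)."""

    mean: np.ndarray
    std: np.ndarray
    scale: np.ndarray
    shift: np.ndarray


@dataclass
class ECMBlockParams:
    """All weights of one enhanced-convolution block, in fusion form."""

    branch3x3: ConvBNBranch
    branch1x1: ConvBNBranch
    branch_id: BNParams | None
    stride: int


def _make_attention(kind: str, channels: int, reduction: int, rng, dtype):
    if kind == "gct":
        return GCT(channels, dtype=dtype)
    if kind == "se":
        return SEBlock(channels, reduction=reduction, rng=rng, dtype=dtype)
    return None


def _bn_to_branch(conv: Conv2d, bn: BatchNorm2d) -> ConvBNBranch:
    std = np.sqrt(bn.running_var + bn.eps)
    return ConvBNBranch(
        kernel=conv.weight.data,
        bias=None if conv.bias is None else conv.bias.data,
        bn_mean=bn.running_mean,
        bn_std=std,
        bn_scale=bn.gamma.data,
        bn_shift=bn.beta.data,
    )


class ECMBlock(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int,
        attention: str = "none",
        se_reduction: int = 16,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.conv3 = Conv2d(in_channels, out_channels, 3, stride, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(out_channels, dtype=dtype)
        self.conv1 = Conv2d(in_channels, out_channels, 1, stride, 0, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.has_identity = stride == 1 and in_channels == out_channels
        self.bn_id = BatchNorm2d(out_channels, dtype=dtype) if self.has_identity else None
        self.attention = _make_attention(attention, out_channels, se_reduction, rng, dtype)
        self.relu = ReLU()

    def _children(self):
        out = [("conv3", self.conv3), ("bn3", self.bn3), ("conv1", self.conv1), ("bn1", self.bn1)]
        if self.bn_id is not None:
            out.append(("bn_id", self.bn_id))
        if self.attention is not None:
            out.append(("attention", self.attention))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.bn3(self.conv3(x, train), train) + self.bn1(self.conv1(x, train), train)
        if self.bn_id is not None:
            y = y + self.bn_id(x, train)
        if self.attention is not None:
            y = self.attention(y, train)
        return self.relu(y, train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad_out)
        if self.attention is not None:
            g = self.attention.backward(g)
        dx = self.conv3.backward(self.bn3.backward(g))
        dx += self.conv1.backward(self.bn1.backward(g))
        if self.bn_id is not None:
            dx += self.bn_id.backward(g)
        return dx

    def export_params(self) -> ECMBlockParams:
        branch_id = None
        if self.bn_id is not None:
            branch_id = BNParams(
                mean=self.bn_id.running_mean,
                std=np.sqrt(self.bn_id.running_var + self.bn_id.eps),
                scale=self.bn_id.gamma.data,
                shift=self.bn_id.beta.data,
            )
        return ECMBlockParams(
            branch3x3=_bn_to_branch(self.conv3, self.bn3),
            branch1x1=_bn_to_branch(self.conv1, self.bn1),
            branch_id=branch_id,
            stride=self.stride,
        )


class PlainBlock(Module):
    """Single 3x3 convolution (+optional bias/attention) followed by ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int,
        bias: bool,
        attention: str = "none",
        se_reduction: int = 16,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.conv = Conv2d(in_channels, out_channels, 3, stride, 1, bias=bias, rng=rng, dtype=dtype)
        self.attention = _make_attention(attention, out_channels, se_reduction, rng, dtype)
        self.relu = ReLU()

    def _children(self):
        out = [("conv", self.conv)]
        if self.attention is not None:
            out.append(("attention", self.attention))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv(x, train)
        if self.attention is not None:
            y = self.attention(y, train)
        return self.relu(y, train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad_out)
        if self.attention is not None:
            g = self.attention.backward(g)
        return self.conv.backward(g)


class TileClassifier(Module):
    """Stacked blocks + global average pool + linear head over tile classes."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.blocks: list[Module] = []
        c_in = config.in_channels
        for depth, width in zip(config.stage_depths, config.stage_widths):
            for layer in range(depth):
                stride = 2 if layer == 0 else 1
                if config.arch == "chain":
                    block = PlainBlock(
                        c_in, width, stride, bias=False,
                        attention=config.attention, se_reduction=config.se_reduction,
                        rng=rng, dtype=dtype,
                    )
                elif config.mode == "deploy":
                    block = PlainBlock(
                        c_in, width, stride, bias=True,
                        attention=config.attention, se_reduction=config.se_reduction,
                        rng=rng, dtype=dtype,
                    )
                else:
                    block = ECMBlock(
                        c_in, width, stride,
                        attention=config.attention, se_reduction=config.se_reduction,
                        rng=rng, dtype=dtype,
                    )
                self.blocks.append(block)
                c_in = width
        self.pool = GlobalAvgPool()
        self.head = Linear(c_in, config.n_classes, rng=rng, dtype=dtype)

    def _children(self):
        return [(f"blocks.{i}", b) for i, b in enumerate(self.blocks)] + [
            ("pool", self.pool),
            ("head", self.head),
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ShapeError(
                f"expected [N,{self.config.in_channels},H,W] input, got {x.shape}"
            )
        h, w = x.shape[2], x.shape[3]
        if h < 32 or w < 32 or h % 32 or w % 32:
            raise ShapeError(f"input spatial dims must be positive multiples of 32, got {h}x{w}")
        for block in self.blocks:
            x = block(x, train)
        return self.head(self.pool(x, train), train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.pool.backward(self.head.backward(grad_out))
        for block in reversed(self.blocks):
            g = block.backward(g)
        return g


def build_model(
    config: ModelConfig,
    seed: int | None = None,
    dtype=np.float32,
) -> TileClassifier:
    """Instantiate a tile classifier from its configuration."""
    rng = np.random.default_rng(0 if seed is None else seed)
    return TileClassifier(config, rng=rng, dtype=dtype)


def count_params(model: Module) -> int:
    """Number of learnable scalars (BN running statistics excluded)."""
    return int(sum(p.size for p in model.parameters()))
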