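"""Structural re-parameterization: exact fusion of the multi-branch training
network into a plain-convolution deployment network.

Each enhanced-convolution block is collapsed in four algebraic steps, none of
which is an approximation:

1. every conv+BN branch becomes a single conv with bias
   (``K' = K * gamma/sigma``, ``B' = (B - mu) * gamma/sigma + beta``),
2. the 1x1 kernel is zero-padded into the centre of a 3x3 kernel,
3. the identity branch becomes a Dirac 3x3 kernel fused with its BN,
4. branch kernels and biases are summed elementwise.

Channel attention sits outside the branch sum, so its parameters pass through
fusion untouched and equivalence is preserved end to end.
"""

from __future__ import annotations

import numpy as np

from .backbone import (
    ConvBNBranch,
    ECMBlock,
    ECMBlockParams,
    PlainBlock,
    TileClassifier,
    build_model,
)
from .errors import ConfigurationError, InvalidStateError, NumericalError, ShapeError


def fuse_conv_bn(branch: ConvBNBranch) -> tuple[np.ndarray, np.ndarray]:
    """Fold a branch's batch normalization into its convolution.

    Returns ``(kernel, bias)`` such that for every input
    ``conv(x, kernel, bias) == bn(conv(x, branch.kernel, branch.bias))``.
    """
    std = np.asarray(branch.bn_std)
    if np.any(std <= 0):
        raise NumericalError("BN standard deviation must be strictly positive")
    scale = branch.bn_scale / std  # per output channel
    kernel = branch.kernel * scale[:, None, None, None]
    bias = np.zeros_like(branch.bn_mean) if branch.bias is None else np.asarray(branch.bias)
    bias = (bias - branch.bn_mean) * scale + branch.bn_shift
    return kernel, bias


def pad_1x1_to_3x3(kernel1: np.ndarray) -> np.ndarray:
    """Embed a 1x1 kernel at the centre of a zero 3x3 kernel."""
    kernel1 = np.asarray(kernel1)
    if kernel1.ndim != 4 or kernel1.shape[2:] != (1, 1):
        raise ShapeError(f"expected [C_out, C_in, 1, 1] kernel, got {kernel1.shape}")
    out = np.zeros(kernel1.shape[:2] + (3, 3), dtype=kernel1.dtype)
    out[:, :, 1, 1] = kernel1[:, :, 0, 0]
    return out


def identity_to_3x3(channels: int, dtype=np.float64) -> np.ndarray:
    """Dirac 3x3 kernel: convolution with it (padding 1, stride 1) is the identity."""
    if channels < 1:
        raise ConfigurationError("channel count must be >= 1")
    kernel = np.zeros((channels, channels, 3, 3), dtype=dtype)
    kernel[np.arange(channels), np.arange(channels), 1, 1] = 1.0
    return kernel


def merge_branches(
    branches: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise-sum branch kernels and biases (linearity of convolution)."""
    if not branches:
        raise ShapeError("need at least one branch to merge")
    k0, b0 = branches[0]
    kernel = np.array(k0, copy=True)
    bias = np.array(b0, copy=True)
    for k, b in branches[1:]:
        if np.shape(k) != kernel.shape or np.shape(b) != bias.shape:
            raise ShapeError("all branches must share kernel and bias shapes")
        kernel += k
        bias += b
    return kernel, bias


def reparameterize_block(ecm: ECMBlockParams) -> tuple[np.ndarray, np.ndarray]:
    """Fuse one enhanced-convolution block into a single 3x3 conv with bias."""
    k3, b3 = fuse_conv_bn(ecm.branch3x3)
    k1, b1 = fuse_conv_bn(ecm.branch1x1)
    branches = [(k3, b3), (pad_1x1_to_3x3(k1), b1)]
    if ecm.branch_id is not None:
        c = ecm.branch_id.mean.shape[0]
        dirac = identity_to_3x3(c, dtype=k3.dtype)
        kid, bid = fuse_conv_bn(
            ConvBNBranch(
                kernel=dirac,
                bias=None,
                bn_mean=ecm.branch_id.mean,
                bn_std=ecm.branch_id.std,
                bn_scale=ecm.branch_id.scale,
                bn_shift=ecm.branch_id.shift,
            )
        )
        branches.append((kid, bid))
    return merge_branches(branches)


def reparameterize_model(train_model: TileClassifier) -> TileClassifier:
    """Convert a train-mode model into its exactly-equivalent deploy model.

    Uses the model's inference-time BN statistics; logits of the two models
    agree to floating-point tolerance for arbitrary inputs.
    """
    cfg = train_model.config
    if cfg.mode != "train" or cfg.arch != "ecm":
        raise InvalidStateError("model is not a train-mode ECM network")
    deploy_cfg = type(cfg)(**{**cfg.to_dict(), "mode": "deploy"})
    dtype = train_model.head.weight.data.dtype
    deploy = build_model(deploy_cfg, seed=0, dtype=dtype)
    for tb, db in zip(train_model.blocks, deploy.blocks):
        assert isinstance(tb, ECMBlock) and isinstance(db, PlainBlock)
        kernel, bias = reparameterize_block(tb.export_params())
        db.conv.weight.data = kernel.astype(dtype)
        db.conv.bias.data = bias.astype(dtype)
        if tb.attention is not None:
            db.attention.load_state_dict(tb.attention.state_dict())
    deploy.head.load_state_dict(train_model.head.state_dict())
    return deploy
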