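"""Exactness of structural re-parameterization.

Every fusion primitive is checked against a direct convolution oracle
(compose-then-compare on random inputs), and the full train-to-deploy
conversion is checked for logit equivalence, idempotent persistence and
monotone compression.
"""

import numpy as np
import pytest

from her2quant import (
    ConvBNBranch,
    ModelConfig,
    build_model,
    count_params,
    fuse_conv_bn,
    identity_to_3x3,
    merge_branches,
    pad_1x1_to_3x3,
    reparameterize_block,
    reparameterize_model,
)
from her2quant.backbone import ECMBlock
from her2quant.errors import (
    ConfigurationError,
    InvalidStateError,
    NumericalError,
    ShapeError,
)
from her2quant.io import load_checkpoint, save_checkpoint
from her2quant.nn import Conv2d

from conftest import randomize_model


def conv_ref(x, kernel, bias=None, stride=1, pad=1):
    """Direct convolution via the Conv2d layer with injected weights."""
    c_out, c_in, k, _ = kernel.shape
    conv = Conv2d(c_in, c_out, k, stride, pad, bias=bias is not None, dtype=kernel.dtype)
    conv.weight.data = kernel
    if bias is not None:
        conv.bias.data = bias
    return conv(x)


def bn_ref(y, mean, std, scale, shift):
    return (y - mean[None, :, None, None]) / std[None, :, None, None] * scale[
        None, :, None, None
    ] + shift[None, :, None, None]


def random_branch(rng, c_out=4, c_in=3, k=3, with_bias=False):
    return ConvBNBranch(
        kernel=rng.normal(0, 1, (c_out, c_in, k, k)),
        bias=rng.normal(0, 1, c_out) if with_bias else None,
        bn_mean=rng.normal(0, 1, c_out),
        bn_std=rng.uniform(0.3, 2.0, c_out),
        bn_scale=rng.uniform(0.5, 1.5, c_out),
        bn_shift=rng.normal(0, 1, c_out),
    )


class TestFuseConvBN:
    def test_identity_bn_leaves_branch_unchanged(self, rng):
        br = random_branch(rng, with_bias=True)
        br.bn_mean[...] = 0.0
        br.bn_std[...] = 1.0
        br.bn_scale[...] = 1.0
        br.bn_shift[...] = 0.0
        k, b = fuse_conv_bn(br)
        assert np.array_equal(k, br.kernel)
        assert np.array_equal(b, br.bias)

    def test_scalar_hand_example(self):
        """K=1, B=0, mu=0.5, sigma=2, gamma=3, beta=1 -> K'=1.5, B'=0.25."""
        br = ConvBNBranch(
            kernel=np.ones((1, 1, 1, 1)),
            bias=np.zeros(1),
            bn_mean=np.array([0.5]),
            bn_std=np.array([2.0]),
            bn_scale=np.array([3.0]),
            bn_shift=np.array([1.0]),
        )
        k, b = fuse_conv_bn(br)
        assert k[0, 0, 0, 0] == pytest.approx(1.5)
        assert b[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("with_bias", [False, True])
    def test_fused_equals_composed(self, rng, with_bias):
        br = random_branch(rng, with_bias=with_bias)
        x = rng.normal(0, 1, (2, 3, 7, 7))
        composed = bn_ref(
            conv_ref(x, br.kernel, br.bias, stride=1, pad=1),
            br.bn_mean, br.bn_std, br.bn_scale, br.bn_shift,
        )
        k, b = fuse_conv_bn(br)
        fused = conv_ref(x, k, b, stride=1, pad=1)
        assert np.abs(fused - composed).max() <= 1e-5

    def test_nonpositive_std_rejected(self, rng):
        br = random_branch(rng)
        br.bn_std[1] = 0.0
        with pytest.raises(NumericalError):
            fuse_conv_bn(br)


class TestPad1x1:
    def test_center_placement(self, rng):
        k1 = rng.normal(0, 1, (3, 2, 1, 1))
        k3 = pad_1x1_to_3x3(k1)
        assert k3.shape == (3, 2, 3, 3)
        assert np.array_equal(k3[:, :, 1, 1], k1[:, :, 0, 0])
        k3[:, :, 1, 1] = 0.0
        assert not k3.any()

    def test_padded_conv_equals_original(self, rng):
        k1 = rng.normal(0, 1, (4, 3, 1, 1))
        x = rng.normal(0, 1, (2, 3, 6, 6))
        out1 = conv_ref(x, k1, stride=1, pad=0)
        out3 = conv_ref(x, pad_1x1_to_3x3(k1), stride=1, pad=1)
        assert np.abs(out1 - out3).max() <= 1e-6

    def test_non_1x1_rejected(self, rng):
        with pytest.raises(ShapeError):
            pad_1x1_to_3x3(rng.normal(0, 1, (2, 2, 3, 3)))


class TestIdentityKernel:
    def test_dirac_structure(self):
        k = identity_to_3x3(2)
        assert np.array_equal(k[:, :, 1, 1], np.eye(2))
        assert k.sum() == 2.0
        k1 = identity_to_3x3(1)
        assert np.array_equal(k1[0, 0], [[0, 0, 0], [0, 1, 0], [0, 0, 0]])

    def test_convolution_is_identity(self, rng):
        x = rng.normal(0, 1, (1, 5, 9, 9))
        out = conv_ref(x, identity_to_3x3(5), stride=1, pad=1)
        assert np.abs(out - x).max() <= 1e-12

    def test_invalid_channels(self):
        with pytest.raises(ConfigurationError):
            identity_to_3x3(0)


class TestMergeBranches:
    def test_single_branch_unchanged(self, rng):
        k, b = rng.normal(0, 1, (2, 2, 3, 3)), rng.normal(0, 1, 2)
        mk, mb = merge_branches([(k, b)])
        assert np.array_equal(mk, k) and np.array_equal(mb, b)

    def test_cancellation(self, rng):
        k, b = rng.normal(0, 1, (2, 2, 3, 3)), rng.normal(0, 1, 2)
        mk, mb = merge_branches([(k, b), (-k, -b)])
        assert not mk.any() and not mb.any()

    def test_merged_conv_equals_sum_of_branch_convs(self, rng):
        branches = [
            (rng.normal(0, 1, (3, 2, 3, 3)), rng.normal(0, 1, 3)) for _ in range(3)
        ]
        x = rng.normal(0, 1, (2, 2, 5, 5))
        summed = sum(conv_ref(x, k, b) for k, b in branches)
        mk, mb = merge_branches(branches)
        assert np.abs(conv_ref(x, mk, mb) - summed).max() <= 1e-5

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            merge_branches(
                [
                    (rng.normal(0, 1, (2, 2, 3, 3)), np.zeros(2)),
                    (rng.normal(0, 1, (3, 2, 3, 3)), np.zeros(3)),
                ]
            )


class TestBlockFusion:
    @pytest.mark.parametrize("stride,attention", [(1, "none"), (2, "none"), (1, "gct"), (2, "se")])
    def test_block_forward_equivalence(self, rng, stride, attention):
        block = randomize_model(
            ECMBlock(4, 4, stride=stride, attention=attention, se_reduction=2,
                     rng=rng, dtype=np.float64),
            rng, dtype=np.float64,
        )
        kernel, bias = reparameterize_block(block.export_params())
        x = rng.normal(0, 1, (2, 4, 8, 8))
        # compare the pre-attention branch sum against the fused convolution
        expected = block.bn3(block.conv3(x)) + block.bn1(block.conv1(x))
        if block.bn_id is not None:
            expected = expected + block.bn_id(x)
        fused = conv_ref(x, kernel, bias, stride=stride, pad=1)
        assert np.abs(fused - expected).max() <= 1e-4

    def test_identity_branch_presence_follows_stride_and_channels(self, rng):
        assert ECMBlock(4, 4, stride=2, rng=rng).export_params().branch_id is None
        assert ECMBlock(4, 8, stride=1, rng=rng).export_params().branch_id is None
        assert ECMBlock(4, 4, stride=1, rng=rng).export_params().branch_id is not None

    def test_zeroed_side_branches_reduce_to_conv_bn_fusion(self, rng):
        block = randomize_model(ECMBlock(4, 4, stride=1, rng=rng, dtype=np.float64),
                                rng, dtype=np.float64)
        # silence the 1x1 and identity branches
        block.conv1.weight.data[...] = 0.0
        block.bn1.gamma.data[...] = 0.0
        block.bn1.beta.data[...] = 0.0
        block.bn_id.gamma.data[...] = 0.0
        block.bn_id.beta.data[...] = 0.0
        kernel, bias = reparameterize_block(block.export_params())
        k3, b3 = fuse_conv_bn(block.export_params().branch3x3)
        assert np.allclose(kernel, k3, atol=1e-12)
        assert np.allclose(bias, b3, atol=1e-12)


class TestModelFusion:
    @pytest.mark.parametrize(
        "dtype,tol", [(np.float32, 1e-4), (np.float64, 1e-9)], ids=["float32", "float64"]
    )
    def test_logit_equivalence(self, dtype, tol):
        worst = 0.0
        for trial in range(3):
            rng = np.random.default_rng(100 + trial)
            cfg = ModelConfig(
                stage_depths=[1, 1, 2, 2, 1], stage_widths=[4, 4, 8, 8, 16],
                attention=["none", "gct", "se"][trial], mode="train", se_reduction=4,
            )
            model = randomize_model(build_model(cfg, seed=trial, dtype=dtype), rng, dtype)
            deploy = reparameterize_model(model)
            x = rng.normal(0, 1, (4, 3, 64, 64)).astype(dtype)
            worst = max(worst, float(np.abs(model(x) - deploy(x)).max()))
        assert worst <= tol

    def test_compression_is_monotone(self, tiny_model_config, rng):
        model = randomize_model(build_model(tiny_model_config, seed=0), rng)
        deploy = reparameterize_model(model)
        assert count_params(deploy) < count_params(model)

    def test_full_architecture_count_drop(self):
        """Fusion shrinks the flagship model from 7,849,142 to 7,049,558 weights."""
        cfg = ModelConfig(attention="gct", mode="train")
        model = build_model(cfg)
        deploy = reparameterize_model(model)
        assert count_params(model) == 7_849_142
        assert count_params(deploy) == 7_049_558

    def test_deploy_model_cannot_be_fused_again(self, tiny_model_config):
        deploy_cfg = ModelConfig(**{**tiny_model_config.to_dict(), "mode": "deploy"})
        with pytest.raises(InvalidStateError):
            reparameterize_model(build_model(deploy_cfg))

    def test_fusion_persistence_is_bit_identical(self, tiny_model_config, rng, tmp_path):
        """Fuse, save, reload, re-run: logits match bit for bit."""
        model = randomize_model(build_model(tiny_model_config, seed=2), rng)
        deploy = reparameterize_model(model)
        path = save_checkpoint(deploy, tmp_path / "deploy.npz")
        reloaded = load_checkpoint(path)
        x = rng.normal(0, 1, (2, 3, 64, 64)).astype(np.float32)
        assert np.array_equal(deploy(x), reloaded(x))

    def test_zero_weight_model_fuses_to_zero(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        for p in model.parameters():
            p.data[...] = 0.0
        deploy = reparameterize_model(model)
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        assert np.array_equal(deploy(x), np.zeros((1, 6), dtype=np.float32))
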