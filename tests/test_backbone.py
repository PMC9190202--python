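"""Architecture contracts: layer counts, closed-form parameter accounting,
attention behaviour, and shape/error handling."""

import numpy as np
import pytest

from her2quant import ModelConfig, build_model, count_params
from her2quant.errors import ConfigurationError, ShapeError
from her2quant.nn import GCT, SEBlock

from conftest import randomize_model


def closed_form_count(depths, widths, n_classes, attention, mode, arch,
                      se_reduction=16, in_channels=3):
    """Independent layer-by-layer parameter arithmetic (the counting oracle)."""
    total = 0
    c_in = in_channels
    layer_channels = []
    for depth, width in zip(depths, widths):
        for layer in range(depth):
            stride = 2 if layer == 0 else 1
            total += width * c_in * 9  # 3x3 kernel
            if arch == "chain":
                pass  # no bias, no BN
            elif mode == "deploy":
                total += width  # conv bias
            else:  # train-mode ECM
                total += width * c_in  # 1x1 kernel
                total += 2 * width * 2  # BN scale+shift on both conv branches
                if stride == 1 and c_in == width:
                    total += 2 * width  # identity-branch BN
            layer_channels.append(width)
            c_in = width
    if attention == "gct":
        total += 3 * sum(layer_channels)
    elif attention == "se":
        total += sum(2 * c * (c // se_reduction) + c // se_reduction + c for c in layer_channels)
    total += widths[-1] * n_classes + n_classes  # head
    return total


PRINTED_COUNTS = [
    # (attention, mode, arch) -> exact learnable-scalar count of the full model
    ("gct", "deploy", "ecm", 7_049_558),
    ("gct", "train", "ecm", 7_849_142),
    ("none", "train", "ecm", 7_835_654),
    ("none", "deploy", "ecm", 7_036_070),
    ("se", "deploy", "ecm", 7_315_631),
    ("none", "train", "chain", 7_031_574),
    ("gct", "train", "chain", 7_045_062),
]


@pytest.mark.parametrize("attention,mode,arch,expected", PRINTED_COUNTS)
def test_full_architecture_parameter_counts(attention, mode, arch, expected):
    """The default architecture reproduces every published Params figure."""
    cfg = ModelConfig(attention=attention, mode=mode, arch=arch)
    model = build_model(cfg)
    n = count_params(model)
    assert n == expected
    assert n == closed_form_count(
        cfg.stage_depths, cfg.stage_widths, cfg.n_classes, attention, mode, arch
    )


@pytest.mark.parametrize("attention", ["none", "gct", "se"])
@pytest.mark.parametrize("mode,arch", [("train", "ecm"), ("deploy", "ecm"), ("train", "chain")])
def test_reduced_architecture_counts_match_closed_form(attention, mode, arch):
    """Brute-force enumeration equals the closed form for every block family."""
    cfg = ModelConfig(
        stage_depths=[1, 2, 1, 2, 1],
        stage_widths=[4, 4, 8, 8, 16],
        attention=attention,
        mode=mode,
        arch=arch,
        se_reduction=4,
    )
    assert count_params(build_model(cfg)) == closed_form_count(
        cfg.stage_depths, cfg.stage_widths, cfg.n_classes, attention, mode, arch,
        se_reduction=4,
    )


def test_layer_count_and_identity_branch_placement():
    cfg = ModelConfig()
    model = build_model(cfg)
    assert len(model.blocks) == 22 == sum(cfg.stage_depths)
    strides = [b.stride for b in model.blocks]
    assert strides.count(2) == 5  # one per stage
    with_id = [getattr(b, "has_identity", False) for b in model.blocks]
    assert sum(with_id) == 17  # stride-1 layers with matching channels


def test_forward_shape_contract(tiny_model_config, rng):
    model = build_model(tiny_model_config, seed=0)
    x = rng.normal(0, 1, (2, 3, 256, 256)).astype(np.float32)
    logits = model(x)
    assert logits.shape == (2, 6)
    # deterministic in inference mode
    assert np.array_equal(logits, model(x))
    with pytest.raises(ShapeError):
        model(rng.normal(0, 1, (2, 3, 100, 100)).astype(np.float32))
    with pytest.raises(ShapeError):
        model(rng.normal(0, 1, (2, 1, 256, 256)).astype(np.float32))


def test_spatial_pyramid_reaches_8x8(tiny_model_config, rng):
    """Five stride-2 layers reduce a 256-px tile to an 8x8 map before pooling."""
    model = build_model(tiny_model_config, seed=0)
    x = rng.normal(0, 1, (1, 3, 256, 256)).astype(np.float32)
    for block in model.blocks:
        x = block(x)
    assert x.shape[2:] == (8, 8)


def test_zero_weight_model_outputs_head_bias(tiny_model_config):
    model = build_model(tiny_model_config, seed=0)
    for p in model.parameters():
        p.data[...] = 0.0
    logits = model(np.zeros((3, 3, 64, 64), dtype=np.float32))
    assert np.array_equal(logits, np.zeros((3, 6), dtype=np.float32))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_classes": 0},
        {"stage_depths": [1, 2, 4]},
        {"stage_widths": [48, 48, 96, 192, 0]},
        {"attention": "cbam"},
        {"mode": "export"},
        {"attention": "se", "stage_widths": [48, 48, 96, 192, 1281]},
    ],
)
def test_invalid_configurations_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        ModelConfig(**kwargs)


class TestGCT:
    def test_identity_at_initialization(self, rng):
        """gamma = beta = 0 makes the tanh gate exactly 1."""
        gct = GCT(5, dtype=np.float64)
        x = rng.normal(0, 2, (3, 5, 7, 7))
        assert np.array_equal(gct(x), x)

    def test_zero_embedding_weight_is_passthrough(self, rng):
        gct = GCT(4, dtype=np.float64)
        gct.alpha.data[...] = 0.0
        gct.gamma.data[:] = rng.normal(0, 1, 4)
        x = rng.normal(0, 1, (2, 4, 6, 6))
        # s_c ~ 0 under the epsilon guard, so the gate stays ~1
        assert np.allclose(gct(x), x, atol=1e-5)

    def test_single_channel_gate_value(self):
        """With C=1 the normalised embedding is 1, so gate = 1 + tanh(1)."""
        gct = GCT(1, eps=1e-12, dtype=np.float64)
        gct.gamma.data[:] = 1.0
        x = np.full((1, 1, 4, 4), 2.0)
        expected = x * (1.0 + np.tanh(1.0))
        assert np.allclose(gct(x), expected, atol=1e-10)

    def test_channel_mismatch(self, rng):
        with pytest.raises(ShapeError):
            GCT(4)(rng.normal(0, 1, (1, 3, 4, 4)))


class TestSE:
    def test_gate_strictly_inside_unit_interval(self, rng):
        se = SEBlock(8, reduction=4, rng=rng, dtype=np.float64)
        x = rng.normal(0, 3, (2, 8, 6, 6))
        out = se(x)
        gates = out[np.abs(x) > 1e-9] / x[np.abs(x) > 1e-9]
        assert gates.min() > 0.0 and gates.max() < 1.0

    def test_zero_parameters_halve_the_input(self, rng):
        se = SEBlock(4, reduction=2, rng=rng, dtype=np.float64)
        for p in se.parameters():
            p.data[...] = 0.0
        x = rng.normal(0, 1, (2, 4, 5, 5))
        assert np.allclose(se(x), 0.5 * x, atol=1e-12)

    def test_param_count_shape_arithmetic(self):
        se = SEBlock(64, reduction=16)
        assert sum(p.size for p in se.parameters()) == 580  # 2*64*4 + 4 + 64

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            SEBlock(10, reduction=4)


def test_state_dict_roundtrip(tiny_model_config, rng):
    model = randomize_model(build_model(tiny_model_config, seed=3), rng)
    clone = build_model(tiny_model_config, seed=9)
    clone.load_state_dict(model.state_dict())
    x = rng.normal(0, 1, (1, 3, 64, 64)).astype(np.float32)
    assert np.array_equal(model(x), clone(x))
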