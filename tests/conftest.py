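import numpy as np
import pytest

from her2quant import ModelConfig, TrainConfig
from her2quant.synthetic import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_config():
    """Smallest architecture that still exercises every block variant."""
    return ModelConfig(
        stage_depths=[1, 1, 2, 2, 1],
        stage_widths=[4, 4, 8, 8, 16],
        attention="none",
        mode="train",
        se_reduction=4,
    )


@pytest.fixture
def quick_train_config():
    return TrainConfig(lr=0.02, batch_size=16, epochs=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic tiles (10 per class) shared across training tests."""
    return generate_dataset(10, seed=5)


def randomize_model(model, rng, dtype=np.float32):
    """Give a model realistic, non-degenerate random weights and BN statistics."""
    for name, p in model.named_parameters():
        if "gamma" in name and "attention" not in name:
            p.data = rng.uniform(0.5, 1.5, p.data.shape).astype(dtype)
        elif name.endswith((".beta", ".bias", ".b_reduce", ".b_expand")):
            p.data = rng.normal(0, 0.1, p.data.shape).astype(dtype)
        elif "attention" in name:
            p.data = rng.normal(0, 0.3, p.data.shape).astype(dtype)
        else:  # conv / linear kernels: jitter around He-scale init
            p.data = (p.data * rng.uniform(0.5, 1.5, p.data.shape)).astype(dtype)
    for name, owner, attr in model.named_buffers():
        arr = np.asarray(getattr(owner, attr))
        if "var" in name:
            setattr(owner, attr, rng.uniform(0.5, 2.0, arr.shape).astype(dtype))
        else:
            setattr(owner, attr, rng.normal(0, 0.2, arr.shape).astype(dtype))
    return model
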