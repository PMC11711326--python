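import numpy as np
import pytest

from cellstyle.models import ModelConfig, StyleTransferModel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TINY_MODEL = dict(
    channels=3,
    img_size=16,
    base_width=4,
    max_width=16,
    style_dim=8,
    noise_dim=4,
)


@pytest.fixture()
def tiny_model():
    """A small untrained model with two drug conditions (16x16 inputs)."""
    cfg = ModelConfig(modalities={"drug": 6}, **TINY_MODEL)
    model = StyleTransferModel(cfg, n_conditions=2, seed=7)
    gen = np.random.default_rng(99)
    for cid in (0, 1):
        model.conditions.add(cid, "drug", vector=gen.standard_normal(6))
    return model
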