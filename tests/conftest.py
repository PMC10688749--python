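import numpy as np
import pytest
from hypothesis import settings

from cellseg import ModelConfig, SegmentationModel, SyntheticSpec, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_pairs():
    """Eight 32x32 synthetic pairs shared across tests."""
    return generate(SyntheticSpec(image_size=32, n_images=8, radius_min=4, radius_max=9, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    """Small full-variant model config for 16x16 inputs."""
    return ModelConfig(
        depth=2, base_channels=4, variant="lr_ccf_fc", patch_size=4,
        embed_dim=8, heads_N=2, rank_L=2,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return SegmentationModel(tiny_config, seed=0)
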