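import numpy as np
import pytest

from maepick import MaeConfig, MaskedAutoencoder, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A model small enough for sub-second forward/backward passes."""
    return MaeConfig(input_size=32, patch_size=8, embed_dim=16, depth=2,
                     n_heads=2, decoder_embed_dim=8, decoder_depth=1)


@pytest.fixture
def tiny_model(tiny_cfg):
    return MaskedAutoencoder(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def small_sim_params():
    """A 512-px micrograph that simulates in well under a second."""
    return SimParams(image_height=512, image_width=512, particle_diameter=48,
                     n_particles=12, snr=2.0, n_contaminants=2,
                     contaminant_scale_range=(16.0, 48.0),
                     min_center_distance=56.0, seed=7)
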