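import numpy as np
import pytest

from hespex.synthetic import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast study conditions for unit-level training tests."""
    return SimConfig(n_types=3, n_genes=12, markers_per_type=3,
                     patch_size=64, n_patches=10,
                     nuclei_per_patch=(4, 8), nucleus_radius=(3.0, 5.0),
                     neighborhood_mixing=0.5, noise_sd=0.15, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)
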