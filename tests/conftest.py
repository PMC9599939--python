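import numpy as np
import pytest

from cnax.synthetic import SyntheticConfig, generate_snp_map


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """A 100-SNP, low-noise cohort config used across unit tests."""
    return SyntheticConfig(n_cases=6, n_snps=100, noise_sd_lrr=0.1, seed=11)


@pytest.fixture
def small_map(small_config):
    return generate_snp_map(small_config)
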