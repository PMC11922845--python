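import numpy as np
import pytest

from coniferdiv.synthetic import SyntheticConfig, generate_species_dataset


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_species=3, n_transcripts_per_species=60, seed=7,
        paralog_snp_rate=0.15,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_species_dataset(small_config, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
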