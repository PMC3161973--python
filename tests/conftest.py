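import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tagdge.synthetic import SyntheticConfig, generate_transcriptome, simulate_libraries


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=120,
        gene_length_range=(150, 600),
        library_size=100_000,
        n_candidates_per_anchor=3,
        n_de_genes=20,
        n_family_decoys=6,
        singleton_noise_tags=300,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(transcriptome, truth, raw libraries) at desk scale, fixed seed."""
    transcriptome, truth = generate_transcriptome(small_config)
    libraries = simulate_libraries(transcriptome, truth, small_config)
    return transcriptome, truth, libraries


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
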