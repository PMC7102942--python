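import numpy as np
import pytest

from affinityqtl.pipeline import run_pipeline
from affinityqtl.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11,
        n_individuals=120,
        n_crm_regions=30,
        genome_length=120_000,
        n_planted_effects=4,
        n_null_genes=8,
        noise_sd=0.4,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    """One full pipeline run shared across tests (deterministic)."""
    return run_pipeline(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
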