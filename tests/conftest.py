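import pytest

from mutseek.config import SimulationConfig
from mutseek.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full synthetic mapping run, shared across tests."""
    return run_pipeline(default_config)


@pytest.fixture(scope="session")
def genome(pipeline_result):
    return pipeline_result.genome


@pytest.fixture(scope="session")
def tiny_config():
    """Small genome for fast repeated simulation."""
    return SimulationConfig(
        seed=1,
        n_chromosomes=2,
        chrom_length_bp=50_000,
        genes_per_chromosome=1,
        causal_chrom_index=0,
        n_background_snps=10,
    )
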