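import numpy as np
import pytest

from impute_eval import SimConfig, breed_population, simulate_founders, simulate_population
from impute_eval.pipeline import make_fixture


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale population used by most integration-style tests."""
    return SimConfig(
        n_founders=24,
        n_samples=60,
        n_chromosomes=2,
        chrom_length_bp=30_000_000,
        n_sites_per_chrom=1_500,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_founders(small_config):
    return simulate_founders(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_founders, small_config):
    return breed_population(small_founders, small_config)


@pytest.fixture(scope="session")
def tiny_panel():
    return make_fixture("tiny-panel")


@pytest.fixture(scope="session")
def exact_copy():
    return make_fixture("exact-copy")


@pytest.fixture(scope="session")
def qc_violations():
    return make_fixture("qc-violations")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
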