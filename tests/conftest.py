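import numpy as np
import pytest

from mucinscan.synthetic import (
    SimProteomeConfig,
    simulate_domain_hits,
    simulate_expression,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def small_proteome():
    """A small proteome with two planted mucins and one decoy of each mode."""
    config = SimProteomeConfig(n_proteins=12, n_true_mucins=2, seed=42)
    records, truth = simulate_proteome(config)
    return config, records, truth


@pytest.fixture(scope="session")
def small_world(small_proteome):
    """Proteome plus noiseless domain hits and expression matrix."""
    config, records, truth = small_proteome
    hits = simulate_domain_hits(truth, fp_rate=0.0, seed=43)
    matrix = simulate_expression(truth, seed=44)
    return records, truth, hits, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
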