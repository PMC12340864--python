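import numpy as np
import pytest

from eqtlpower import simulate_expression_study, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_study():
    """A 2,000-individual study with one planted signal (r = 0.25)."""
    g = simulate_genotypes(2000, 12, 0.3, ld_rho=0.2, seed=11)
    study = simulate_expression_study(g, [(4, 0.25)], noise_seed=12)
    return study
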