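import numpy as np
import pytest

from paralogy.ks import codon_align
from paralogy.simulate import (MixtureTruth, SimulationConfig,
                               simulate_codon_pair, simulate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by the integration-style tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_families=30,
                                             library_sizes=1500))


@pytest.fixture(scope="session")
def aligned_pair_ks05():
    """Aligned codon columns of one simulated pair at true Ks = 0.5."""
    a, b = simulate_codon_pair(500, 0.5, omega=0.2, kappa=2.0, seed=1)
    return codon_align(a, b)


@pytest.fixture(scope="session")
def default_truth():
    return MixtureTruth()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
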