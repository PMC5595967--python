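import numpy as np
import pytest

from cycleprof.synthcyto import DMSO_TRUTH, PhaseFractions, PopulationModel, simulate_well


@pytest.fixture
def default_model():
    return PopulationModel(g1_mean=100.0, cv=0.05, n_events=10000, seed=7)


@pytest.fixture
def dmso_well():
    """One vehicle-control well at the default screen settings."""
    return simulate_well(DMSO_TRUTH, PopulationModel(seed=7, n_events=5000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fingerprint_values(rng, n):
    """n random four-phase percentage rows summing to 100."""
    raw = rng.dirichlet(np.ones(4), size=n) * 100.0
    return raw


@pytest.fixture
def g1_only_well():
    return simulate_well(PhaseFractions(1, 0, 0, 0), PopulationModel(seed=3, n_events=10000))
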