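import numpy as np
import pytest

from alupoly.insertmodel import InsertSizeModel
from alupoly.library import AluLibrary
from alupoly.simulate import SimulationConfig, build_population_and_trios


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_model():
    return InsertSizeModel(mean=400.0, sd=50.0, epsilon=0.005)


@pytest.fixture
def library():
    return AluLibrary.synthetic(np.random.default_rng(7), length=300)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale population: 300 kb, 10 sites, 10 haploids / 5 diploids."""
    config = SimulationConfig(
        ref_length=300_000, n_haploids=10, sites_per_consensus=2, seed=1
    )
    return build_population_and_trios(config)


@pytest.fixture(scope="session")
def trio_cohort():
    """Three trios on a 400 kb reference."""
    config = SimulationConfig(
        ref_length=400_000, sites_per_consensus=2, seed=2, n_trios=3
    )
    return build_population_and_trios(config, targets=("all",))
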