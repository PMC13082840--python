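import numpy as np
import pytest

from submort.data import MortalityDataset
from submort.model import ModelConfig
from submort.simulate import SimulationConfig, basis_from_curves, generate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small synthetic dataset with truth, shared across unit tests."""
    cfg = SimulationConfig(n_areas=3, n_years=4, n_subpops=3, n_ages=5, seed=7)
    data, truth = generate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def tiny_basis(tiny_sim):
    _, _, truth = tiny_sim
    return basis_from_curves(truth.curves)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Hand-built 2x2x2x3 dataset including a zero-exposure cell."""
    rng = np.random.default_rng(0)
    shape = (2, 2, 2, 3)
    expo = rng.uniform(500, 5000, size=shape)
    expo[0, 0, 0, 0] = 0.0
    lam = np.full(shape, 0.01)
    deaths = rng.poisson(expo * lam)
    deaths[0, 0, 0, 0] = 0
    return MortalityDataset(
        deaths=deaths,
        exposures=expo,
        ages=["0-39", "40+"],
        subpops=["female", "male"],
        areas=["a1", "a2"],
        years=[2001, 2002, 2003],
    )
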