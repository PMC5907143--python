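import numpy as np
import pytest
from hypothesis import settings

from pnndiffusion import Rect, SimScenario, make_pairwise_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_dataset():
    """Small uniform pairwise dataset: D = 1 um^2/s, rho = 1/um^2, 10 pairs."""
    scenario = SimScenario.uniform(1.0, states=((1.0, 1.0),), seed=2024)
    dataset, truth = make_pairwise_dataset(scenario)
    return scenario, dataset, truth


@pytest.fixture
def aoi():
    return Rect(0, 0, 10, 10)
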