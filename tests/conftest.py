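import numpy as np
import pytest

from bispeed.pipelines import decoder_for_population, tuning_curves_from_population
from bispeed.synthetic_data import make_population


@pytest.fixture(scope="session")
def population100():
    return make_population(100, seed=1)


@pytest.fixture(scope="session")
def tuning_curves(population100):
    return tuning_curves_from_population(population100)


@pytest.fixture(scope="session")
def decoder(population100, tuning_curves):
    return decoder_for_population(population100, tuning_curves)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
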