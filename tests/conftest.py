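import numpy as np
import pytest

from esptools.synthetic import generate_preset


@pytest.fixture(scope="session")
def titration_1b_noiseless():
    series, truth = generate_preset("1b-abs", seed=0, noise_sigma=0.0)
    return series, truth


@pytest.fixture(scope="session")
def lippert_1a_clean():
    pairs, truth = generate_preset("lippert-1a", seed=0)
    return pairs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
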