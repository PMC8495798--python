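import numpy as np
import pytest

from seedbankhmm import DesignSpec, ModelSpec, fit, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """8 plots x 6 species x 6 years with the default generative truth."""
    dataset, truth = generate_dataset(DesignSpec.small(seed=101))
    return dataset, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short two-chain fit of the small dataset, reused across tests."""
    dataset, truth = small_dataset
    spec = ModelSpec(iterations=400, burn_in=150, seed=7)
    return fit(dataset, spec), dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
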