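import logging

import numpy as np
import pytest

from mirlink import SynthConfig, generate_dataset

logging.getLogger("mirlink").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset shared across tests."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A reduced study design for fast end-to-end runs."""
    return SynthConfig(
        p_mirna=60, p_mrna=40, n_de_mirna=9, n_de_mrna=5,
        n_modules=2, module_size=(2, 2), seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
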