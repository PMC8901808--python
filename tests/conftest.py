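import numpy as np
import pytest

from slnrad.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small signal-bearing cohort shared across tests (read-only)."""
    config = PhantomConfig(n_train=24, n_val=12, n_test=6, seed=11)
    studies, manifest = generate_cohort(config)
    return config, studies, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
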