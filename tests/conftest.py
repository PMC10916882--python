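import numpy as np
import pytest
from hypothesis import settings

from sixmm.sampling import build_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def micro_dataset():
    """Small oscillation-filtered dataset shared across tests."""
    ds = build_dataset(64, seed=5)
    assert len(ds) > 20
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
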