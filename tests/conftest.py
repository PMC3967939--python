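import numpy as np
import pytest

from chromcode import random_sparse_model, sample_dataset
from chromcode.model_core import exact_log_partition


@pytest.fixture(scope="session")
def small_model():
    """Random sparse pairwise model on 10 factors with exact logZ."""
    m = random_sparse_model(10, pair_density=0.2, seed=3)
    m.logZ = exact_log_partition(m)
    return m


@pytest.fixture(scope="session")
def small_data(small_model):
    return sample_dataset(small_model, 20_000, seed=7, method="exact")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
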