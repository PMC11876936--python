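import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests import local oracles

from lesionfuse.phantoms import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams(grid_shape=(16, 32, 32), seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """20 phantoms (10 per class) on the reduced grid."""
    return generate_cohort(small_params, n_per_class=10, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
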