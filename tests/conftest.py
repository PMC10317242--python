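import numpy as np
import pytest

from feddna.data import SyntheticSpec, generate_synthetic, minmax_scale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_layers(rng):
    """Three sites, four nodes, five dims of random weights."""
    return [rng.normal(size=(4, 5)) for _ in range(3)]


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated two-class table on which a small net trains easily."""
    table = generate_synthetic(
        SyntheticSpec(n_samples=300, n_features=10, class_separation=3.0), seed=7
    )
    return minmax_scale(table)
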