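import numpy as np
import pytest

from minicol import ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_internal_config():
    """A scaled-down internal-representation config for fast unit tests."""
    return ExperimentConfig(
        I=100, n_mc=5, C=4, S_max=800, n_objects=5,
        mode="internal_rep", n_patterns=20, n_runs=2, seed=7,
    )


@pytest.fixture
def small_hierarchical_config():
    return ExperimentConfig(
        I=100, n_mc=5, C=4, S_max=800, F=10.0, n_objects=5,
        mode="hierarchical", n_patterns=20, n_runs=2, seed=7,
    )
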