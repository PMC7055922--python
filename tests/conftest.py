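import numpy as np
import pytest

from hicsr import (
    ContactMatrix, default_config, downsample, make_synthetic_chromosome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng) -> ContactMatrix:
    """Random symmetric 12-bin Poisson count matrix."""
    upper = np.triu(rng.poisson(20, size=(12, 12)).astype(float))
    return ContactMatrix("chrT", 10_000, upper + np.triu(upper, 1).T)


@pytest.fixture(scope="session")
def fixture_pair():
    """One default synthetic chromosome and its 1/16-downsampled version."""
    cfg = default_config(seed=7)
    truth = make_synthetic_chromosome(cfg)
    low = downsample(truth, 1 / 16, seed=8)
    return cfg, truth, low
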