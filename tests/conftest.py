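import numpy as np
import pytest

import promkic as pk


@pytest.fixture(scope="session")
def small_fixture_set():
    """Two labeled synthetic promoters per class (20 sequences)."""
    return pk.make_fixture_set(2, seed=7)


@pytest.fixture(scope="session")
def small_rasters(small_fixture_set):
    rasters = [
        pk.rasterize(pk.build_pattern(s), binarize=False)
        for s, _ in small_fixture_set
    ]
    labels = [lab for _, lab in small_fixture_set]
    return rasters, labels


@pytest.fixture(scope="session")
def small_model(small_rasters):
    rasters, labels = small_rasters
    return pk.train(rasters, labels, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
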