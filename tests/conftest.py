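import numpy as np
import pytest

from goldmapper import build_locus


@pytest.fixture(scope="session")
def big_locus():
    """The full-size study geometry: 4.1 kb arms, 50 bp loop, 2 edits."""
    return build_locus(10_000, 4_100, 50, 2, 5_000, seed=1)


@pytest.fixture(scope="session")
def small_locus():
    """A scaled-down locus for read-level tests."""
    return build_locus(2_000, 400, 50, 2, 1_000, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
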