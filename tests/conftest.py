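import numpy as np
import pytest

from hseqtl.markers import MarkerMap, default_marker_map
from hseqtl.popsim import simulate_cross


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """Three chromosomes, six markers each, 10 cM spacing."""
    return default_marker_map(3, 6, 10.0)


@pytest.fixture(scope="session")
def hscc_pop(small_map):
    """One HS-CC cohort (96 individuals) reused across read-only tests."""
    return simulate_cross("HSCC", small_map, seed=7)


@pytest.fixture(scope="session")
def hscc_geno(hscc_pop):
    return hscc_pop.genotypes(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
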