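import numpy as np
import pytest

from sf6dval.lattice import DEFAULT_LATTICE, LatticeSpec


@pytest.fixture(scope="session")
def default_spec() -> LatticeSpec:
    return DEFAULT_LATTICE


@pytest.fixture(scope="session")
def tiny_spec() -> LatticeSpec:
    """A 2^6 lattice small enough for exhaustive checks."""
    return LatticeSpec((2, 2, 2, 2, 2, 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
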