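import numpy as np
import pytest

from resetdyn.experiments import (
    FixtureSpec,
    double_well_fixture,
    generate_fixture,
    make_config,
    START,
    STOP,
)


@pytest.fixture(scope="session")
def fast_fixture():
    """Scaled-down landscape with a cached unbiased baseline (sub-ns MFPT)."""
    return generate_fixture(FixtureSpec(), seed=11)


@pytest.fixture(scope="session")
def dw_surface():
    """Quartic double well on which standard SR gives no acceleration."""
    return double_well_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
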