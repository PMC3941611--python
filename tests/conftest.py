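import numpy as np
import pytest

from betacv.synthetic import FixtureSpec, toy_complex

# Modest sphere-point count keeps ASA-heavy tests quick; resolution is a
# documented parameter and the convergence test covers the default.
ASA_POINTS = 240


@pytest.fixture(scope="session")
def toy():
    """Two-chain mini-complex, no waters."""
    return toy_complex(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_bound_water():
    return toy_complex(FixtureSpec(seed=1, water="bound"))


@pytest.fixture(scope="session")
def toy_free_water():
    return toy_complex(FixtureSpec(seed=1, water="free"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
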