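import numpy as np
import pytest

import nirpls as n
from nirpls.simulate import interval_recovery_fixture


@pytest.fixture(scope="session")
def fixture75():
    """The default 75-sample, 2800-variable noisy fixture."""
    return n.default_fixture()


@pytest.fixture(scope="session")
def noiseless75():
    """Noiseless full-scale fixture: exact Beer-Lambert mixtures."""
    return n.simulate_dataset(noise=n.NoiseSpec.none(), seed=42)


@pytest.fixture(scope="session")
def small_recovery():
    """Reduced-grid fixture with interval-confined ground truth."""
    return interval_recovery_fixture(seed=1)


@pytest.fixture(scope="session")
def small_noiseless():
    """Reduced-grid, rank-3, noiseless mixture with y = total content."""
    return interval_recovery_fixture(seed=3, noise=n.NoiseSpec.none())


@pytest.fixture()
def rng():
    return np.random.default_rng(20150414)
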