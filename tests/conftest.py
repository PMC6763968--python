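import numpy as np
import pytest

import arcfa


@pytest.fixture(scope="session")
def layout():
    return arcfa.minipip_layout()


@pytest.fixture(scope="session")
def moments():
    return arcfa.minipip_fixture()


@pytest.fixture(scope="session")
def ic_fit(layout, moments):
    """IC-CFA fitted to the embedded mini-IPIP moments (shared; read-only)."""
    return arcfa.fit(arcfa.build_ic_cfa(layout), moments)


@pytest.fixture(scope="session")
def ar_fit(layout, moments):
    """AR-CFA (adjacent + construct-specific) fitted to the embedded moments."""
    return arcfa.fit(arcfa.build_ar_cfa(layout, "adjacent_plus_construct"), moments)


@pytest.fixture(scope="session")
def baseline(moments):
    return arcfa.baseline_fit(moments)


@pytest.fixture
def rng():
    return np.random.default_rng(20190920)


def random_pd(rng, p):
    """Random well-conditioned positive-definite matrix."""
    a = rng.standard_normal((p, p + 3))
    return a @ a.T / (p + 3) + 0.5 * np.eye(p)
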