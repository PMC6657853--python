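import numpy as np
import pytest

import conesim as cs
import conesim.params as bp


@pytest.fixture(scope="session")
def geom():
    return cs.ConeGeometry()


@pytest.fixture(scope="session")
def params():
    return cs.default_params()


@pytest.fixture(scope="session")
def derived(params, geom):
    return bp.derived_rates(params, geom.eps0, geom.nu)


@pytest.fixture(scope="session")
def dark(params, derived):
    return bp.solve_dark_state(params, derived)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
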