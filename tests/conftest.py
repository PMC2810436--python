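"""Shared fixtures: small equilibrated communities generated at test time."""
import numpy as np
import pytest

from neutralsar import equilibrate, make_params


@pytest.fixture(scope="session")
def params_desk():
    """Fast desk-scale regime used by most simulator tests."""
    return make_params(0.2, 1.0, 0.5)


@pytest.fixture(scope="session")
def community_desk(params_desk):
    """One equilibrated community at alpha=0.2 (N ~ 4000)."""
    return equilibrate(params_desk, None, 40.0, seed=11)


@pytest.fixture(scope="session")
def params_a005():
    return make_params(0.05, 1.0, 0.25)


@pytest.fixture(scope="session")
def community_a005(params_a005):
    """Equilibrated alpha=0.05 community (N ~ 18000) shared by the
    simulator-versus-theory suites."""
    return equilibrate(params_a005, None, 60.0, seed=101)
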