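"""Shared fixtures: the toy system and fitted scans are session-scoped
because LP scans are the expensive part of the suite."""

import pytest

from camtransit import (
    CamTransitionModel,
    make_env_profile,
    make_toy_cell_network,
)


@pytest.fixture(scope="session")
def toy_net():
    return make_toy_cell_network()


@pytest.fixture(scope="session")
def default_env():
    return make_env_profile()


@pytest.fixture(scope="session")
def toy_model():
    """Unfitted model facade under default study conditions."""
    return CamTransitionModel.from_toy()


@pytest.fixture(scope="session")
def combined(toy_model):
    """The assembled LP model (charge + aperture + water attached)."""
    return toy_model.combined


@pytest.fixture(scope="session")
def results(toy_model):
    """Full default fit: C3 reference, scan, classification, storage."""
    return toy_model.fit()
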