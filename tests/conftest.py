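import pytest

from grasstox.engine import DEFAULT_PARAMS, Grid
from grasstox.herbicide import default_dose_responses
from grasstox.traits import default_pfts, pft_map


@pytest.fixture(scope="session")
def pfts():
    return default_pfts()


@pytest.fixture(scope="session")
def pmap(pfts):
    return pft_map(pfts)


@pytest.fixture(scope="session")
def doses():
    """Packaged reference dose-response parameters (both herbicides)."""
    return default_dose_responses()


@pytest.fixture()
def mono_grid():
    """Default 7x7 monoculture pot at mid-sweep resource levels."""
    return Grid(7, 7, above_resource=75.0, below_resource=90.0)


@pytest.fixture()
def params():
    return DEFAULT_PARAMS
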