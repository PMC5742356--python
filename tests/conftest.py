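import warnings

import pytest

from scfvtools.fixture import build_tracking_fixture
from scfvtools.germline import build_fixture_reference
from scfvtools.simulate import LibrarySimConfig, simulate_library

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def refdir():
    return build_fixture_reference(1)


@pytest.fixture(scope="session")
def small_library(refdir):
    config = LibrarySimConfig(n_clones=8, seed=3)
    clones, freqs = simulate_library(refdir, config)
    return config, clones, freqs


@pytest.fixture(scope="session")
def tracking_fixture():
    return build_tracking_fixture(0)
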