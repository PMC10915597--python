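import numpy as np
import pytest

from refugia.engine import SampleConfig
from refugia.models import build_catalog


@pytest.fixture(scope="session")
def catalog():
    """Full default model catalog, keyed by name."""
    return {m.name: m for m in build_catalog("full")}


@pytest.fixture(scope="session")
def null_params():
    return {"Ne_A": 2e5, "Ne_B": 2e5, "Ne_C": 2e5,
            "tdiv_AB": 3e6, "tdiv_ABC": 3.5e6}


@pytest.fixture(scope="session")
def sample12():
    return SampleConfig(12, 12, 12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
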