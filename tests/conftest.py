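import numpy as np
import pytest

import sleepsig as ss
from sleepsig.synthetic import CouplingSpec


@pytest.fixture(scope="session")
def atlas20():
    return ss.generate_atlas(20, seed=1)


@pytest.fixture(scope="session")
def atlas8():
    return ss.generate_atlas(8, seed=1)


@pytest.fixture(scope="session")
def cohort200():
    """Default-coupling cohort reused across association-level tests."""
    return ss.generate_phenotypes(200, seed=11)


@pytest.fixture(scope="session")
def null_coupling():
    return CouplingSpec.null()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
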