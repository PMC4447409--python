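import numpy as np
import pytest

from ivim_ablate.synthetic_cohort import (
    default_geometry,
    default_ground_truth,
    default_protocol,
)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def b_values(protocol):
    return np.asarray(protocol.b_values, dtype=float)


@pytest.fixture(scope="session")
def truth_table():
    return default_ground_truth()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
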