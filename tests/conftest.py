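import numpy as np
import pytest

from oligocna.io import read_arm_table
from oligocna.synthetic import make_probe_set


@pytest.fixture(scope="session")
def arms():
    return read_arm_table()


@pytest.fixture(scope="session")
def probes_small(arms):
    """2200-probe scaffold (100 per autosome), fixed seed."""
    return make_probe_set(100, seed=11, arms=arms)


@pytest.fixture(scope="session")
def probes_medium(arms):
    """4400-probe scaffold used where breakpoint precision matters."""
    return make_probe_set(200, seed=12, arms=arms)
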