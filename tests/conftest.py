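import numpy as np
import pytest

from eemcc.hierarchy import build_hierarchy
from eemcc.synthetic import (dipeptide_topology, make_solvated_dipeptide,
                             make_water_box_frames, water_topology)


@pytest.fixture(scope="session")
def dipeptide():
    top = dipeptide_topology()
    return top, build_hierarchy(top)


@pytest.fixture(scope="session")
def water_box():
    top, batch = make_water_box_frames(216, n_frames=2, seed=11)
    return top, build_hierarchy(top), batch


@pytest.fixture(scope="session")
def solvated():
    top, batch = make_solvated_dipeptide(n_frames=3, n_waters=64, seed=7)
    return top, build_hierarchy(top), batch


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_waters():
    top = water_topology(2)
    return top, build_hierarchy(top)
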