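import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from rnacg import ForceField, build_topology
from rnacg.fixtures import make_duplex, make_single_helix


@pytest.fixture(scope="session")
def ff():
    return ForceField.default()


@pytest.fixture(scope="session")
def duplex6(ff):
    return make_duplex("GCGCGC")


@pytest.fixture(scope="session")
def duplex6_top(duplex6, ff):
    return build_topology(duplex6, set(ff.hbond.pairs))


@pytest.fixture(scope="session")
def helix4():
    return make_single_helix("ACGU")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
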