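import numpy as np
import pytest

from lcdphase.forcefield import make_forcefield


@pytest.fixture(scope="session")
def ff():
    """Default force field (310 K, 100 mM) shared across tests."""
    return make_forcefield()


@pytest.fixture(scope="session")
def ff_short():
    """Short-cutoff force field for small-box simulation tests."""
    return make_forcefield(cutoff_vdw=25.0, cutoff_elec=25.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
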