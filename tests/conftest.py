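import numpy as np
import pytest

from dsbdesign.synthetic import (make_harmonic_ensemble, make_helix_chain,
                                 make_oligomer, plant_interface_pair)


@pytest.fixture(scope="session")
def helix20():
    return make_helix_chain(20)


@pytest.fixture(scope="session")
def hexamer(helix20):
    """Trimer-of-dimers hexamer (6 chains, exact D3-style symmetry)."""
    return make_oligomer(helix20, 3, dimerize=True)


@pytest.fixture(scope="session")
def planted_hexamer(helix20):
    """Hexamer with a same-position dimer-interface pair planted at 6.5 A."""
    return plant_interface_pair(helix20, 6.5)


@pytest.fixture(scope="session")
def small_ensemble(helix20):
    """200-frame harmonic ensemble, sigma = 0.3 A everywhere."""
    return make_harmonic_ensemble(helix20, np.full(20, 0.3), 200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
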