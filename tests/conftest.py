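import numpy as np
import pytest

from zwitterslide import fixtures
from zwitterslide.forcefield import ForceField


@pytest.fixture(scope="session")
def mini12_neutral():
    """Charge-free miniature bilayer big enough for minimum-image dynamics."""
    return fixtures.mini_system(12, charge_on=False, seed=0).config


@pytest.fixture(scope="session")
def mini12_charged():
    return fixtures.mini_system(12, charge_on=True, seed=0).config


@pytest.fixture(scope="session")
def mini8_charged():
    return fixtures.mini_system(8, charge_on=True, seed=0).config


@pytest.fixture(scope="session")
def jiggled_mini12(mini12_neutral):
    """Thermal-looking snapshot: built positions plus a small seeded jiggle
    (avoids the exact symmetry/equilibrium zeros of the pristine lattice)."""
    rng = np.random.default_rng(7)
    pos = mini12_neutral.positions + 0.015 * rng.standard_normal(
        mini12_neutral.positions.shape)
    return pos


@pytest.fixture(scope="session")
def ff_mini12(mini12_neutral):
    return ForceField(mini12_neutral)
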