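import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from metamorph import TraitVector, load_preset, solve_equilibrium


@pytest.fixture(scope="session")
def fat():
    return load_preset("fat_reserves")


@pytest.fixture(scope="session")
def generic():
    return load_preset("generic_invertebrate")


@pytest.fixture(scope="session")
def toy():
    return load_preset("toy_symmetric")


@pytest.fixture(scope="session")
def meta_traits():
    """A metamorphosing strategy near the CSS of the fat-reserves preset."""
    return TraitVector(psi_L=0.0, theta=1.0, w_J=0.0229, w_b=0.0068)


@pytest.fixture(scope="session")
def dd_traits():
    """A direct-development strategy (born past the metamorphosis mass)."""
    return TraitVector(psi_L=1.0, theta=0.0, w_J=0.0102, w_b=0.03)


@pytest.fixture(scope="session")
def meta_equilibrium(fat, meta_traits):
    return solve_equilibrium(meta_traits, fat)
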