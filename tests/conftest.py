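"""Shared fixtures: toy potentials and synthetic databases."""

import numpy as np
import pytest

from mlpot.data import Atom, Molecule
from mlpot.toys import ToyPotential, generate_database, make_diatomic

MORSE_PARAMS = dict(De=0.17, a=1.9, r0=0.95)


@pytest.fixture
def morse():
    return ToyPotential("morse", **MORSE_PARAMS)


@pytest.fixture
def harmonic():
    return ToyPotential("harmonic_bond", k=0.5, r0=1.0)


@pytest.fixture
def diatomic():
    return make_diatomic(0.95)


@pytest.fixture
def morse_db(morse, diatomic):
    """10 diatomic geometries with exact Morse energies + gradients."""
    return generate_database(
        morse, diatomic, 10, seed=1, mode="uniform_bond", bond_range=(0.75, 1.4)
    )


@pytest.fixture
def morse_test_db(morse, diatomic):
    """Held-out pool from the same distribution, different seed."""
    return generate_database(
        morse, diatomic, 40, seed=7, mode="uniform_bond", bond_range=(0.75, 1.4)
    )


@pytest.fixture
def triatomic():
    """Equilateral H3-like cluster with 0.95 A sides."""
    r0 = 0.95
    return Molecule(
        [
            Atom("H", [0.0, 0.0, 0.0]),
            Atom("H", [r0, 0.0, 0.0]),
            Atom("H", [r0 / 2, r0 * np.sqrt(3) / 2, 0.0]),
        ]
    )


@pytest.fixture
def water_like():
    """Bent triatomic (no symmetry constraints used anywhere)."""
    return Molecule(
        [
            Atom("H", [0.76, 0.59, 0.0]),
            Atom("O", [0.0, 0.0, 0.0]),
            Atom("H", [-0.76, 0.59, 0.0]),
        ]
    )
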