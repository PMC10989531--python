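import math

import numpy as np
import pytest

from jcoupling import (
    MolecularStructure,
    SimulatorParams,
    generate_structures,
    simulate_couplings,
    template_structure,
)

_T = 1.09 / math.sqrt(3.0)


@pytest.fixture
def methane():
    """Ideal tetrahedral methane, C–H 1.09 Å; atom 0 is the carbon."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [_T, _T, _T],
        [_T, -_T, -_T],
        [-_T, _T, -_T],
        [-_T, -_T, _T],
    ])
    return MolecularStructure("methane", ("C", "H", "H", "H", "H"), coords)


@pytest.fixture
def ethane():
    """Staggered ethane at ideal geometry."""
    return template_structure("ethane")


@pytest.fixture
def water():
    """Water with O at the origin; the two H span a 104.5 degree angle."""
    a = math.radians(104.5)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.96, 0.0, 0.0],
        [0.96 * math.cos(a), 0.96 * math.sin(a), 0.0],
    ])
    return MolecularStructure("water", ("O", "H", "H"), coords)


@pytest.fixture
def benzene():
    """Planar benzene (C–C 1.39 Å, C–H 1.09 Å); carbons first."""
    elements, coords = [], []
    for k in range(6):
        a = math.pi / 3 * k
        elements.append("C")
        coords.append([1.39 * math.cos(a), 1.39 * math.sin(a), 0.0])
    for k in range(6):
        a = math.pi / 3 * k
        elements.append("H")
        coords.append([2.48 * math.cos(a), 2.48 * math.sin(a), 0.0])
    return MolecularStructure("benzene", tuple(elements), np.array(coords))


@pytest.fixture(scope="session")
def small_dataset():
    """60 jittered synthetic molecules with simulated constants (σ = 0.1 Hz)."""
    structures = generate_structures(60, seed=7)
    couplings = simulate_couplings(structures, SimulatorParams(seed=7, noise_sd=0.1))
    return structures, couplings


def random_rigid_motion(rng: np.random.Generator):
    """A uniform random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=5.0, size=3)


def apply_rigid_motion(structure: MolecularStructure, rot, shift) -> MolecularStructure:
    return MolecularStructure(
        structure.molecule_id, structure.elements, structure.coords @ rot.T + shift
    )
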