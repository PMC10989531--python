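"""Synthetic molecules and simulated coupling constants with known ground truth.

Molecules are built from five hard-coded small-molecule templates (ethane,
propane, ethanol, ethylamine, fluoroethane) held as internal coordinates
(Z-matrices).  Each generated conformer jitters bond lengths (σ = 0.02 Å)
and bond angles (σ = 3°) and rotates every rotatable-bond dihedral by a
uniform angle on [0°, 360°).

Coupling constants follow closed-form geometric laws so the learning task has
a known answer:

* 1J: ``base + slope · (r − 1.09)`` in the bond length r;
* 2J: ``base + coeff · cos(φ)`` in the angle φ at the intervening atom;
* 3J: the Karplus law ``A·cos²θ + B·cosθ + C`` in the path dihedral θ;

each plus Gaussian noise of standard deviation ``noise_sd`` Hz.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import BondGraph, perceive_bonds
from .io import (
    CouplingRecord,
    CouplingTable,
    MolecularStructure,
    write_couplings_csv,
    write_structures_csv,
)

__all__ = [
    "SimulatorParams",
    "TEMPLATE_NAMES",
    "template_structure",
    "generate_structures",
    "karplus_coupling",
    "simulate_couplings",
    "make_fixture_dataset",
    "bond_angle",
    "dihedral_angle",
]


@dataclass(frozen=True)
class SimulatorParams:
    """Constants of the closed-form coupling laws (Hz) and the noise level."""

    karplus_a: float = 7.0
    karplus_b: float = -1.0
    karplus_c: float = 5.0
    onebond_base: float = 125.0
    onebond_slope: float = -50.0  # Hz per Å away from 1.09 Å
    twobond_base: float = -12.0
    twobond_angle_coeff: float = 5.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Internal-coordinate templates
# ---------------------------------------------------------------------------

# Z-matrix rows: (element, a, r) / (element, a, r, b, angle_deg)
# / (element, a, r, b, angle_deg, c, dihedral_deg, rotor_id).
# The new atom X is bonded to a at distance r, makes angle X-a-b, and torsion
# X-a-b-c.  Rows sharing a rotor_id receive one common uniform dihedral offset
# (a rigid rotation of that terminal group).
_ZMatRow = tuple

_TEMPLATES: Dict[str, List[_ZMatRow]] = {
    "ethane": [
        ("C",),
        ("C", 0, 1.54),
        ("H", 0, 1.09, 1, 109.47),
        ("H", 0, 1.09, 1, 109.47, 2, 120.0, None),
        ("H", 0, 1.09, 1, 109.47, 2, 240.0, None),
        ("H", 1, 1.09, 0, 109.47, 2, 60.0, "me2"),
        ("H", 1, 1.09, 0, 109.47, 2, 180.0, "me2"),
        ("H", 1, 1.09, 0, 109.47, 2, 300.0, "me2"),
    ],
    "propane": [
        ("C",),
        ("C", 0, 1.53),
        ("C", 1, 1.53, 0, 112.0),
        ("H", 0, 1.09, 1, 109.47, 2, 60.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 180.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 300.0, "me0"),
        ("H", 1, 1.09, 2, 109.47, 0, 121.0, None),
        ("H", 1, 1.09, 2, 109.47, 0, 239.0, None),
        ("H", 2, 1.09, 1, 109.47, 0, 60.0, "me2"),
        ("H", 2, 1.09, 1, 109.47, 0, 180.0, "me2"),
        ("H", 2, 1.09, 1, 109.47, 0, 300.0, "me2"),
    ],
    "ethanol": [
        ("C",),
        ("C", 0, 1.51),
        ("O", 1, 1.43, 0, 108.5),
        ("H", 2, 0.96, 1, 108.5, 0, 180.0, "oh"),
        ("H", 0, 1.09, 1, 109.47, 2, 60.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 180.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 300.0, "me0"),
        ("H", 1, 1.09, 2, 109.47, 0, 121.0, None),
        ("H", 1, 1.09, 2, 109.47, 0, 239.0, None),
    ],
    "ethylamine": [
        ("C",),
        ("C", 0, 1.53),
        ("N", 1, 1.47, 0, 110.0),
        ("H", 2, 1.01, 1, 109.5, 0, 60.0, "nh2"),
        ("H", 2, 1.01, 1, 109.5, 0, 300.0, "nh2"),
        ("H", 0, 1.09, 1, 109.47, 2, 60.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 180.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 300.0, "me0"),
        ("H", 1, 1.09, 2, 109.47, 0, 121.0, None),
        ("H", 1, 1.09, 2, 109.47, 0, 239.0, None),
    ],
    "fluoroethane": [
        ("C",),
        ("C", 0, 1.50),
        ("F", 1, 1.38, 0, 109.5),
        ("H", 0, 1.09, 1, 109.47, 2, 60.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 180.0, "me0"),
        ("H", 0, 1.09, 1, 109.47, 2, 300.0, "me0"),
        ("H", 1, 1.09, 2, 109.47, 0, 121.0, None),
        ("H", 1, 1.09, 2, 109.47, 0, 239.0, None),
    ],
}

TEMPLATE_NAMES: Tuple[str, ...] = tuple(_TEMPLATES)


def _place_atom(a, b, c, r, theta, phi):
    """Place an atom at distance r from a, angle theta (X-a-b), torsion phi (X-a-b-c)."""
    u = a - b
    u /= np.linalg.norm(u)
    w = b - c
    n = np.cross(w, u)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # collinear reference frame; pick any perpendicular
        n = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(u, np.array([0.0, 1.0, 0.0]))
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, u)
    # -cos(theta) along a-b so the X-a-b angle comes out as theta
    direction = (
        -math.cos(theta) * u
        + math.sin(theta) * math.cos(phi) * m
        - math.sin(theta) * math.sin(phi) * n
    )
    return a + r * direction


def _zmat_to_cartesian(rows: Sequence[_ZMatRow]) -> np.ndarray:
    coords = np.zeros((len(rows), 3))
    for k, row in enumerate(rows):
        if k == 0:
            continue
        if k == 1:
            coords[1] = [row[2], 0.0, 0.0]
            continue
        if k == 2 or len(row) == 5:
            _, a, r, b, ang = row[:5]
            theta = math.radians(ang)
            # in-plane placement using a dummy out-of-plane reference
            u = coords[b] - coords[a]
            u /= np.linalg.norm(u)
            perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-10:
                perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
            perp /= np.linalg.norm(perp)
            coords[k] = coords[a] + r * (math.cos(theta) * u + math.sin(theta) * perp)
            continue
        _, a, r, b, ang, c, dih = row[:7]
        coords[k] = _place_atom(
            coords[a], coords[b], coords[c], r, math.radians(ang), math.radians(dih)
        )
    return coords


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in radians."""
    u, v = p0 - p1, p2 - p1
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in radians, in (-π, π]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(math.atan2(y, x))


def template_structure(name: str, molecule_id: Optional[str] = None) -> MolecularStructure:
    """The unjittered, ideal-geometry structure of one template."""
    rows = _TEMPLATES[name]
    coords = _zmat_to_cartesian(rows)
    return MolecularStructure(
        molecule_id or name, tuple(r[0] for r in rows), coords
    )


def _jittered_structure(name: str, molecule_id: str, rng: np.random.Generator) -> MolecularStructure:
    rows = _TEMPLATES[name]
    rotors = sorted({r[7] for r in rows if len(r) == 8 and r[7] is not None})
    offsets = {rot: rng.uniform(0.0, 360.0) for rot in rotors}
    jittered: List[_ZMatRow] = []
    for row in rows:
        if len(row) == 1:
            jittered.append(row)
            continue
        r = rng.normal(row[2], 0.02)
        if len(row) == 3:
            jittered.append((row[0], row[1], r))
            continue
        ang = rng.normal(row[4], 3.0)
        if len(row) == 5:
            jittered.append((row[0], row[1], r, row[3], ang))
            continue
        dih = row[6] + (offsets[row[7]] if row[7] is not None else 0.0)
        jittered.append((row[0], row[1], r, row[3], ang, row[5], dih))
    coords = _zmat_to_cartesian(jittered)
    return MolecularStructure(molecule_id, tuple(r[0] for r in rows), coords)


def generate_structures(n: int, seed: int = 0) -> Dict[str, MolecularStructure]:
    """Generate n jittered conformers, templates assigned round-robin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: Dict[str, MolecularStructure] = {}
    for k in range(n):
        name = TEMPLATE_NAMES[k % len(TEMPLATE_NAMES)]
        mol_id = f"synth_{k:06d}_{name}"
        out[mol_id] = _jittered_structure(name, mol_id, rng)
    return out


def karplus_coupling(theta: float, params: SimulatorParams) -> float:
    """Karplus law A·cos²θ + B·cosθ + C for a dihedral θ in radians."""
    c = math.cos(theta)
    return params.karplus_a * c * c + params.karplus_b * c + params.karplus_c


def _shortest_path_atoms(
    graph: BondGraph, i: int, j: int, n: int
) -> Tuple[int, ...]:
    """Intermediate atoms of the n-bond path i..j, lowest-index tie-break."""
    adj = graph.adjacency()
    if n == 1:
        return ()
    if n == 2:
        common = sorted(set(adj[i]) & set(adj[j]))
        return (common[0],)
    # n == 3: neighbors a of i and b of j with a-b bonded, lexicographic min
    candidates = sorted(
        (a, b)
        for a in adj[i]
        for b in adj[j]
        if a != j and b != i and a != b and b in adj[a]
    )
    return candidates[0]


def _true_coupling(
    structure: MolecularStructure, graph: BondGraph, record: CouplingRecord,
    params: SimulatorParams,
) -> float:
    i, j = record.atom_index_0, record.atom_index_1
    n = int(record.coupling_type[0])
    coords = structure.coords
    if n == 1:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        return params.onebond_base + params.onebond_slope * (r - 1.09)
    if n == 2:
        (k,) = _shortest_path_atoms(graph, i, j, 2)
        phi = bond_angle(coords[i], coords[k], coords[j])
        return params.twobond_base + params.twobond_angle_coeff * math.cos(phi)
    a, b = _shortest_path_atoms(graph, i, j, 3)
    theta = dihedral_angle(coords[i], coords[a], coords[b], coords[j])
    return karplus_coupling(theta, params)


def simulate_couplings(
    structures: Dict[str, MolecularStructure],
    params: Optional[SimulatorParams] = None,
) -> CouplingTable:
    """Enumerate all coupling pairs and assign constants by the geometric laws.

    Molecules are processed in sorted-id order so the noise stream is
    reproducible for a given seed.
    """
    from .graph import enumerate_pairs

    params = params or SimulatorParams()
    rng = np.random.default_rng(params.seed)
    records: List[CouplingRecord] = []
    for mol_id in sorted(structures):
        structure = structures[mol_id]
        graph = perceive_bonds(structure)
        for rec in enumerate_pairs(structure, graph):
            value = _true_coupling(structure, graph, rec, params)
            if params.noise_sd > 0:
                value += rng.normal(0.0, params.noise_sd)
            records.append(rec.with_constant(value))
    return CouplingTable(records)


def make_fixture_dataset(
    n_molecules: int,
    seed: int = 0,
    out_dir: str = ".",
    params: Optional[SimulatorParams] = None,
) -> Tuple[str, str]:
    """Write a structures.csv + couplings.csv fixture pair; returns the paths."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    params = params or SimulatorParams(seed=seed)
    structures = generate_structures(n_molecules, seed=seed)
    couplings = simulate_couplings(structures, params)
    os.makedirs(out_dir, exist_ok=True)
    structures_path = os.path.join(out_dir, "structures.csv")
    couplings_path = os.path.join(out_dir, "couplings.csv")
    write_structures_csv(structures, structures_path)
    write_couplings_csv(couplings, couplings_path)
    return structures_path, couplings_path
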