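"""Covalent-bond perception from 3D coordinates and coupling-pair classification.

Bonds are perceived with the usual covalent-radius criterion: atoms i and j
are bonded iff ``dist(i, j) <= r_cov(el_i) + r_cov(el_j) + tolerance``.  The
number of bonds separating two atoms (shortest bond path) determines the
coupling order n of an nJ coupling; only n in {1, 2, 3} with a partner element
in {H, C, N} belongs to the eight-type taxonomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import CouplingRecord, CouplingTable, MolecularStructure

__all__ = [
    "COVALENT_RADII",
    "DEFAULT_TOLERANCE",
    "BondGraph",
    "perceive_bonds",
    "bond_path_length",
    "classify_coupling",
    "enumerate_pairs",
]

logger = logging.getLogger(__name__)

#: Single-bond covalent radii in Å (Pyykkö-style).
COVALENT_RADII: Dict[str, float] = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57}

#: Default slack added to the sum of covalent radii, Å.
DEFAULT_TOLERANCE = 0.40


@dataclass(frozen=True)
class BondGraph:
    """Undirected bond adjacency over atom indices ``0..n_atoms-1``."""

    n_atoms: int
    edges: FrozenSet[Tuple[int, int]]  # each (i, j) with i < j

    def __post_init__(self):
        edges = frozenset(tuple(sorted(e)) for e in self.edges)
        for i, j in edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n_atoms} atoms")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bonds(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> List[int]:
        """Sorted neighbor list of atom i."""
        out = [b if a == i else a for a, b in self.edges if i in (a, b)]
        return sorted(out)

    def adjacency(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {i: [] for i in range(self.n_atoms)}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return {i: sorted(v) for i, v in adj.items()}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g


def perceive_bonds(
    structure: MolecularStructure, tolerance: float = DEFAULT_TOLERANCE
) -> BondGraph:
    """Perceive covalent bonds with the covalent-radius distance criterion."""
    n = structure.n_atoms
    if n == 1:
        return BondGraph(1, frozenset())
    radii = np.array([COVALENT_RADII[el] for el in structure.elements])
    dist = squareform(pdist(structure.coords))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return BondGraph(n, frozenset(zip(ii.tolist(), jj.tolist())))


def bond_path_length(graph: BondGraph, i: int, j: int) -> Optional[int]:
    """Shortest path between atoms i and j in bond steps; None if disconnected."""
    if i == j:
        raise ValueError("bond path length of an atom to itself is undefined")
    try:
        return nx.shortest_path_length(graph.to_networkx(), i, j)
    except nx.NetworkXNoPath:
        return None


def classify_coupling(
    structure: MolecularStructure, graph: BondGraph, i: int, j: int
) -> Optional[str]:
    """Classify the (H at i, atom j) pair into the eight-type taxonomy.

    Returns the canonical type string (e.g. ``"3JCH"``) or None when the pair
    is outside the taxonomy (partner not in {H, C, N}, or more than three
    bonds apart, or disconnected).
    """
    if structure.element(i) != "H":
        raise ValueError(f"atom {i} is {structure.element(i)}, not H")
    partner = structure.element(j)
    if partner not in ("H", "C", "N"):
        return None
    n = bond_path_length(graph, i, j)
    if n is None or n > 3:
        return None
    if partner == "H":
        # two hydrogens one bond apart (H2) fall outside the taxonomy
        return f"{n}JHH" if n >= 2 else None
    return f"{n}J{partner}H"


def enumerate_pairs(structure: MolecularStructure, graph: BondGraph) -> CouplingTable:
    """Enumerate every classifiable (H, partner) pair of the molecule.

    Each unordered pair appears once; for HH pairs the lower index is
    ``atom_index_0``.  Records are ordered by (atom_index_0, atom_index_1).
    """
    g = graph.to_networkx()
    records = []
    for h in range(structure.n_atoms):
        if structure.element(h) != "H":
            continue
        lengths = nx.single_source_shortest_path_length(g, h, cutoff=3)
        for j, n in lengths.items():
            if j == h or n < 1:
                continue
            partner = structure.element(j)
            if partner not in ("H", "C", "N"):
                continue
            if partner == "H" and (j < h or n < 2):
                continue  # count each HH pair once; directly bonded H2 excluded
            ctype = f"{n}J{partner}H" if partner != "H" else f"{n}JHH"
            records.append(CouplingRecord(structure.molecule_id, h, j, ctype))
    records.sort(key=lambda r: (r.atom_index_0, r.atom_index_1))
    return CouplingTable(records)


def check_supplied_types(
    structure: MolecularStructure, graph: BondGraph, table: CouplingTable
) -> None:
    """Warn when a supplied coupling type disagrees with the perceived graph.

    The supplied label always wins; the perceived classification is advisory
    (mirroring a pipeline that trusts its dataset's labels).
    """
    for rec in table:
        if rec.molecule_id != structure.molecule_id:
            continue
        perceived = classify_coupling(structure, graph, rec.atom_index_0, rec.atom_index_1)
        if perceived != rec.coupling_type:
            logger.warning(
                "molecule %s pair (%d, %d): supplied type %s, perceived %s; "
                "keeping the supplied type",
                rec.molecule_id, rec.atom_index_0, rec.atom_index_1,
                rec.coupling_type, perceived,
            )
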