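"""Atom-pair descriptor computation for scalar-coupling regression.

A coupling record is featurized into a fixed, named vector built from five
blocks (proposed mode):

* 210 molecular descriptors: molecule size counts, a frozen subset of the
  RDKit molecule-level descriptor battery, and per-target-atom properties
  (degree, ring membership, hybridization, aromaticity, element identity, ...);
* 1 Euclidean distance between the target atoms (Å);
* 49 statistics over the pair distances of all same-type couplings in the
  molecule (mean/min/max/std, differences, quotients, counts, ranks);
* 12 distances from the pair midpoint to the six nearest O and six nearest N
  atoms;
* 24 distances from each target atom to its six nearest O and six nearest N
  atoms.

When a requested heteroatom does not exist in the molecule the distance slot
holds the sentinel value 1000.  For HH-type couplings the 24 target-atom
distances are replaced by a 17-value block of environment averages over the
two hydrogens; for NH types the trivially-informative nearest-N slot of the
nitrogen target is removed.  The "traditional" mode (the chemical-shift
baseline) keeps only the 210 molecular descriptors and the pair distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as _RD, rdDetermineBonds
from rdkit.Geometry import Point3D

from .graph import BondGraph, perceive_bonds
from .io import CouplingRecord, CouplingTable, MolecularStructure

__all__ = [
    "SENTINEL_DISTANCE",
    "DescriptorVector",
    "FeaturizationError",
    "pair_distance",
    "knn_heteroatom_distances",
    "midpoint_descriptors",
    "target_atom_descriptors",
    "same_type_distance_descriptors",
    "standard_molecular_descriptors",
    "hh_replacement_descriptors",
    "featurize",
    "featurize_table",
    "feature_names",
    "variance_filter",
    "MOLECULAR_DESCRIPTOR_NAMES",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Distance recorded when a requested heteroatom does not exist, Å.
SENTINEL_DISTANCE = 1000.0

#: Neighbors kept per heteroatom element (6 O + 6 N = 12 midpoint slots,
#: 2 atoms x 12 = 24 target-atom slots).
KNN_K = 6


class FeaturizationError(RuntimeError):
    """Raised when a molecule cannot be featurized; carries the molecule id."""

    def __init__(self, molecule_id: str, message: str):
        super().__init__(f"molecule {molecule_id!r}: {message}")
        self.molecule_id = molecule_id


@dataclass(frozen=True)
class DescriptorVector:
    """Named, ordered feature values for one coupling record."""

    names: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if len(self.names) != values.shape[0]:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("descriptor values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


# ---------------------------------------------------------------------------
# Frozen name lists
# ---------------------------------------------------------------------------

# Molecule-level RDKit descriptor battery subset, frozen by name so the block
# is stable across toolkit releases (BCUT2D_* excluded: they raise on inputs
# that fail charge perception).
RDKIT_BATTERY_NAMES = (
    'MaxAbsEStateIndex',
    'MaxEStateIndex',
    'MinAbsEStateIndex',
    'MinEStateIndex',
    'qed',
    'SPS',
    'MolWt',
    'HeavyAtomMolWt',
    'ExactMolWt',
    'NumValenceElectrons',
    'NumRadicalElectrons',
    'MaxPartialCharge',
    'MinPartialCharge',
    'MaxAbsPartialCharge',
    'MinAbsPartialCharge',
    'FpDensityMorgan1',
    'FpDensityMorgan2',
    'FpDensityMorgan3',
    'AvgIpc',
    'BalabanJ',
    'BertzCT',
    'Chi0',
    'Chi0n',
    'Chi0v',
    'Chi1',
    'Chi1n',
    'Chi1v',
    'Chi2n',
    'Chi2v',
    'Chi3n',
    'Chi3v',
    'Chi4n',
    'Chi4v',
    'HallKierAlpha',
    'Ipc',
    'Kappa1',
    'Kappa2',
    'Kappa3',
    'LabuteASA',
    'PEOE_VSA1',
    'PEOE_VSA10',
    'PEOE_VSA11',
    'PEOE_VSA12',
    'PEOE_VSA13',
    'PEOE_VSA14',
    'PEOE_VSA2',
    'PEOE_VSA3',
    'PEOE_VSA4',
    'PEOE_VSA5',
    'PEOE_VSA6',
    'PEOE_VSA7',
    'PEOE_VSA8',
    'PEOE_VSA9',
    'SMR_VSA1',
    'SMR_VSA10',
    'SMR_VSA2',
    'SMR_VSA3',
    'SMR_VSA4',
    'SMR_VSA5',
    'SMR_VSA6',
    'SMR_VSA7',
    'SMR_VSA8',
    'SMR_VSA9',
    'SlogP_VSA1',
    'SlogP_VSA10',
    'SlogP_VSA11',
    'SlogP_VSA12',
    'SlogP_VSA2',
    'SlogP_VSA3',
    'SlogP_VSA4',
    'SlogP_VSA5',
    'SlogP_VSA6',
    'SlogP_VSA7',
    'SlogP_VSA8',
    'SlogP_VSA9',
    'TPSA',
    'EState_VSA1',
    'EState_VSA10',
    'EState_VSA11',
    'EState_VSA2',
    'EState_VSA3',
    'EState_VSA4',
    'EState_VSA5',
    'EState_VSA6',
    'EState_VSA7',
    'EState_VSA8',
    'EState_VSA9',
    'VSA_EState1',
    'VSA_EState10',
    'VSA_EState2',
    'VSA_EState3',
    'VSA_EState4',
    'VSA_EState5',
    'VSA_EState6',
    'VSA_EState7',
    'VSA_EState8',
    'VSA_EState9',
    'FractionCSP3',
    'HeavyAtomCount',
    'NHOHCount',
    'NOCount',
    'NumAliphaticCarbocycles',
    'NumAliphaticHeterocycles',
    'NumAliphaticRings',
    'NumAromaticCarbocycles',
    'NumAromaticHeterocycles',
    'NumAromaticRings',
    'NumHAcceptors',
    'NumHDonors',
    'NumHeteroatoms',
    'NumRotatableBonds',
    'NumSaturatedCarbocycles',
    'NumSaturatedHeterocycles',
    'NumSaturatedRings',
    'RingCount',
    'MolLogP',
    'MolMR',
    'fr_Al_COO',
    'fr_Al_OH',
    'fr_Al_OH_noTert',
    'fr_ArN',
    'fr_Ar_COO',
    'fr_Ar_N',
    'fr_Ar_NH',
    'fr_Ar_OH',
    'fr_COO',
    'fr_COO2',
    'fr_C_O',
    'fr_C_O_noCOO',
    'fr_C_S',
    'fr_HOCCN',
    'fr_Imine',
    'fr_NH0',
    'fr_NH1',
    'fr_NH2',
    'fr_N_O',
    'fr_Ndealkylation1',
    'fr_Ndealkylation2',
    'fr_Nhpyrrole',
    'fr_SH',
    'fr_aldehyde',
    'fr_alkyl_carbamate',
    'fr_alkyl_halide',
    'fr_allylic_oxid',
    'fr_amide',
    'fr_amidine',
    'fr_aniline',
    'fr_aryl_methyl',
    'fr_azide',
    'fr_azo',
    'fr_barbitur',
    'fr_benzene',
    'fr_benzodiazepine',
    'fr_bicyclic',
    'fr_diazo',
    'fr_dihydropyridine',
    'fr_epoxide',
    'fr_ester',
    'fr_ether',
    'fr_furan',
    'fr_guanido',
    'fr_halogen',
    'fr_hdrzine',
    'fr_hdrzone',
    'fr_imidazole',
    'fr_imide',
    'fr_isocyan',
    'fr_isothiocyan',
    'fr_ketone',
    'fr_ketone_Topliss',
    'fr_lactam',
    'fr_lactone',
)

_PER_ATOM_PROPS = (
    "degree", "n_h_neighbors", "in_ring", "aromatic",
    "hyb_sp", "hyb_sp2", "hyb_sp3", "hyb_other",
    "is_H", "is_C", "is_N", "is_O", "is_F",
    "formal_charge", "ring3", "ring4", "ring5", "ring6",
)

#: The 210 molecular-descriptor names: 2 size counts + 172 battery entries
#: + 18 per-atom properties for each of the two target atoms.
MOLECULAR_DESCRIPTOR_NAMES: Tuple[str, ...] = (
    ("mol_num_atoms", "mol_num_bonds")
    + tuple(f"rdkit_{n}" for n in RDKIT_BATTERY_NAMES)
    + tuple(f"atom0_{p}" for p in _PER_ATOM_PROPS)
    + tuple(f"atom1_{p}" for p in _PER_ATOM_PROPS)
)
assert len(MOLECULAR_DESCRIPTOR_NAMES) == 210

PAIR_DISTANCE_NAME = "pair_distance"

_ST_GROUPS = ("mol", "h", "partner")
_ST_STATS = (
    "count", "mean", "min", "max", "std", "sum", "range",
    "d_minus_mean", "d_minus_min", "d_minus_max", "d_minus_std",
    "d_over_mean", "d_over_min", "d_over_max", "rank",
)

#: The 49 same-type distance statistics: 15 per grouping (all same-type pairs
#: in the molecule / those sharing the hydrogen / those sharing the partner)
#: plus two cross-group mean differences and two group-size fractions.
SAME_TYPE_NAMES: Tuple[str, ...] = tuple(
    f"st_{g}_{s}" for g in _ST_GROUPS for s in _ST_STATS
) + (
    "st_h_mean_minus_mol_mean",
    "st_partner_mean_minus_mol_mean",
    "st_h_count_frac",
    "st_partner_count_frac",
)
assert len(SAME_TYPE_NAMES) == 49

MIDPOINT_NAMES: Tuple[str, ...] = tuple(
    f"mid_{el}_{k}" for el in ("O", "N") for k in range(1, KNN_K + 1)
)
TARGET_ATOM_NAMES: Tuple[str, ...] = tuple(
    f"atom{t}_{el}_{k}" for t in (0, 1) for el in ("O", "N") for k in range(1, KNN_K + 1)
)
HH_REPLACEMENT_NAMES: Tuple[str, ...] = tuple(
    f"hh_{el}_{k}" for el in ("O", "N") for k in range(1, KNN_K + 1)
) + ("hh_nearest_cn", "hh_st_mean", "hh_st_min", "hh_st_max", "hh_st_std")

#: Slot removed for NH types: the nitrogen target's nearest-N distance.
NH_REMOVED_NAME = "atom1_N_1"

_HH_TYPES = ("2JHH", "3JHH")
_NH_TYPES = ("1JNH", "2JNH", "3JNH")


def feature_names(coupling_type: str, mode: str = "proposed") -> Tuple[str, ...]:
    """The frozen, ordered descriptor-name list for one type and mode.

    Lengths: 296 for CH types, 295 for NH types (nearest-N slot removed),
    289 for HH types (24 target-atom slots replaced by 17 averages), and 211
    in traditional mode for every type.
    """
    if mode == "traditional":
        return MOLECULAR_DESCRIPTOR_NAMES + (PAIR_DISTANCE_NAME,)
    if mode != "proposed":
        raise ValueError(f"unknown featurization mode {mode!r}")
    base = MOLECULAR_DESCRIPTOR_NAMES + (PAIR_DISTANCE_NAME,) + SAME_TYPE_NAMES + MIDPOINT_NAMES
    if coupling_type in _HH_TYPES:
        return base + HH_REPLACEMENT_NAMES
    tail = TARGET_ATOM_NAMES
    if coupling_type in _NH_TYPES:
        tail = tuple(n for n in tail if n != NH_REMOVED_NAME)
    return base + tail


# ---------------------------------------------------------------------------
# Geometric blocks
# ---------------------------------------------------------------------------

def pair_distance(structure: MolecularStructure, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j in Å."""
    if i == j:
        raise ValueError("distance of an atom to itself is undefined")
    return float(np.linalg.norm(structure.coords[i] - structure.coords[j]))


def knn_heteroatom_distances(
    structure: MolecularStructure,
    point: np.ndarray,
    element: str,
    k: int = KNN_K,
    exclude: Iterable[int] = (),
) -> List[float]:
    """Distances from a point to the k nearest atoms of an element, ascending.

    Slots beyond the available atom count are padded with the sentinel 1000.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = set(exclude)
    idx = [
        a for a, el in enumerate(structure.elements)
        if el == element and a not in excluded
    ]
    if not idx:
        return [SENTINEL_DISTANCE] * k
    d = np.linalg.norm(structure.coords[idx] - np.asarray(point, dtype=float), axis=1)
    d = np.sort(d)[:k]
    return list(d) + [SENTINEL_DISTANCE] * (k - len(d))


def midpoint_descriptors(structure: MolecularStructure, record: CouplingRecord) -> List[float]:
    """12 distances from the pair midpoint to the nearest O atoms then N atoms."""
    mid = 0.5 * (structure.coords[record.atom_index_0] + structure.coords[record.atom_index_1])
    return (
        knn_heteroatom_distances(structure, mid, "O")
        + knn_heteroatom_distances(structure, mid, "N")
    )


def target_atom_descriptors(structure: MolecularStructure, record: CouplingRecord) -> List[float]:
    """24 distances: per target atom, its 6 nearest O then 6 nearest N atoms.

    Each target atom is excluded from its own candidate list; HH types use
    :func:`hh_replacement_descriptors` instead.
    """
    if record.coupling_type in _HH_TYPES:
        raise ValueError("HH types use hh_replacement_descriptors")
    out: List[float] = []
    for a in (record.atom_index_0, record.atom_index_1):
        p = structure.coords[a]
        out += knn_heteroatom_distances(structure, p, "O", exclude=(a,))
        out += knn_heteroatom_distances(structure, p, "N", exclude=(a,))
    return out


def _group_stats(dists: np.ndarray, d: float) -> List[float]:
    mean = float(dists.mean())
    lo = float(dists.min())
    hi = float(dists.max())
    std = float(dists.std())  # population std
    rank = float(np.sum(dists < d) + 1)
    return [
        float(len(dists)), mean, lo, hi, std, float(dists.sum()), hi - lo,
        d - mean, d - lo, d - hi, d - std,
        d / mean, d / lo, d / hi, rank,
    ]


def same_type_distance_descriptors(
    same_type_records: Sequence[CouplingRecord],
    record: CouplingRecord,
    structure: MolecularStructure,
) -> List[float]:
    """49 statistics over pair distances of same-type couplings in the molecule.

    Three groupings are used: all same-type records, those sharing the
    record's hydrogen (``atom_index_0``) and those sharing its partner
    (``atom_index_1``).  Per grouping: count, mean, min, max, population std,
    sum, range, the difference of the record's own distance d with each of
    mean/min/max/std, the quotient of d with each of mean/min/max (distances
    are strictly positive; std never appears as a denominator), and the
    1-based rank of d within the group.  Four cross-group values complete the
    49.  A singleton group is legal: mean=min=max=d, std=0, rank=1.
    """
    recs = list(same_type_records)
    if not any(r.pair_key == record.pair_key for r in recs):
        raise ValueError("record must be among the supplied same-type records")
    dists = np.array([pair_distance(structure, r.atom_index_0, r.atom_index_1) for r in recs])
    d = pair_distance(structure, record.atom_index_0, record.atom_index_1)
    mask_h = np.array([record.atom_index_0 in (r.atom_index_0, r.atom_index_1) for r in recs])
    mask_p = np.array([record.atom_index_1 in (r.atom_index_0, r.atom_index_1) for r in recs])
    g_all, g_h, g_p = dists, dists[mask_h], dists[mask_p]
    out = _group_stats(g_all, d) + _group_stats(g_h, d) + _group_stats(g_p, d)
    out += [
        float(g_h.mean() - g_all.mean()),
        float(g_p.mean() - g_all.mean()),
        float(len(g_h)) / len(g_all),
        float(len(g_p)) / len(g_all),
    ]
    return out


def _per_atom_same_type_stats(
    atom: int,
    same_type_records: Sequence[CouplingRecord],
    structure: MolecularStructure,
) -> np.ndarray:
    dists = np.array([
        pair_distance(structure, r.atom_index_0, r.atom_index_1)
        for r in same_type_records
        if atom in (r.atom_index_0, r.atom_index_1)
    ])
    return np.array([dists.mean(), dists.min(), dists.max(), dists.std()])


def hh_replacement_descriptors(
    structure: MolecularStructure,
    graph: BondGraph,
    record: CouplingRecord,
    same_type_records: Sequence[CouplingRecord],
) -> List[float]:
    """17 replacement values for HH couplings (both targets are hydrogens).

    Elementwise average over the two hydrogens of their 12 nearest-O/N
    distances, the averaged distance to each hydrogen's nearest carbon or
    nitrogen atom, and the averaged per-hydrogen same-type distance
    mean/min/max/std.
    """
    if record.coupling_type not in _HH_TYPES:
        raise ValueError(f"{record.coupling_type} is not an HH type")
    pair = (record.atom_index_0, record.atom_index_1)
    knn_blocks, nearest_cn, st_stats = [], [], []
    for a in pair:
        p = structure.coords[a]
        knn_blocks.append(
            knn_heteroatom_distances(structure, p, "O", exclude=(a,))
            + knn_heteroatom_distances(structure, p, "N", exclude=(a,))
        )
        cn = [
            d for d in (
                knn_heteroatom_distances(structure, p, "C", k=1, exclude=(a,))[0],
                knn_heteroatom_distances(structure, p, "N", k=1, exclude=(a,))[0],
            )
        ]
        nearest_cn.append(min(cn))
        st_stats.append(_per_atom_same_type_stats(a, same_type_records, structure))
    avg_knn = (np.array(knn_blocks[0]) + np.array(knn_blocks[1])) / 2.0
    avg_st = (st_stats[0] + st_stats[1]) / 2.0
    return list(avg_knn) + [float(np.mean(nearest_cn))] + list(avg_st)


# ---------------------------------------------------------------------------
# Toolkit molecular block
# ---------------------------------------------------------------------------

_HYB = Chem.HybridizationType


def build_toolkit_mol(structure: MolecularStructure, graph: BondGraph) -> Chem.Mol:
    """Build an RDKit molecule from elements + the perceived bond graph.

    Bond orders are inferred from the connectivity and geometry; when order
    assignment fails (e.g. radical fragments) the molecule keeps single bonds
    and only ring/hybridization perception is run.
    """
    rw = Chem.RWMol()
    for el in structure.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in sorted(graph.edges):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(structure.n_atoms)
    for i, (x, y, z) in enumerate(structure.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    try:
        rdDetermineBonds.DetermineBondOrders(mol, charge=0)
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        pass
    # fallback: single bonds, partial sanitization (rings + hybridization)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_SYMMRINGS
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
            | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION,
        )
    except Exception as exc:
        raise FeaturizationError(structure.molecule_id, f"toolkit construction failed: {exc}")
    return mol


def _battery_values(mol: Chem.Mol) -> np.ndarray:
    funcs = dict(_RD._descList)
    out = np.empty(len(RDKIT_BATTERY_NAMES))
    for k, name in enumerate(RDKIT_BATTERY_NAMES):
        try:
            v = float(funcs[name](mol))
        except Exception:
            v = 0.0
        out[k] = v if np.isfinite(v) else 0.0
    return out


def _atom_props(mol: Chem.Mol, idx: int) -> np.ndarray:
    atom = mol.GetAtomWithIdx(idx)
    hyb = atom.GetHybridization()
    sym = atom.GetSymbol()
    return np.array([
        atom.GetDegree(),
        sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"),
        float(atom.IsInRing()),
        float(atom.GetIsAromatic()),
        float(hyb == _HYB.SP),
        float(hyb == _HYB.SP2),
        float(hyb == _HYB.SP3),
        float(hyb not in (_HYB.SP, _HYB.SP2, _HYB.SP3)),
        float(sym == "H"), float(sym == "C"), float(sym == "N"),
        float(sym == "O"), float(sym == "F"),
        float(atom.GetFormalCharge()),
        float(atom.IsInRingSize(3)), float(atom.IsInRingSize(4)),
        float(atom.IsInRingSize(5)), float(atom.IsInRingSize(6)),
    ])


def standard_molecular_descriptors(
    structure: MolecularStructure,
    graph: BondGraph,
    record: CouplingRecord,
    _mol: Optional[Chem.Mol] = None,
    _battery: Optional[np.ndarray] = None,
) -> List[float]:
    """The 210 toolkit-derived molecular descriptors for one record.

    ``_mol``/``_battery`` allow a caller to reuse per-molecule work when
    featurizing many records of the same molecule.
    """
    mol = _mol if _mol is not None else build_toolkit_mol(structure, graph)
    battery = _battery if _battery is not None else _battery_values(mol)
    head = np.array([structure.n_atoms, graph.n_bonds], dtype=float)
    a0 = _atom_props(mol, record.atom_index_0)
    a1 = _atom_props(mol, record.atom_index_1)
    return list(np.concatenate([head, battery, a0, a1]))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def featurize(
    structure: MolecularStructure,
    graph: BondGraph,
    record: CouplingRecord,
    mode: str = "proposed",
    same_type_records: Optional[Sequence[CouplingRecord]] = None,
    _mol: Optional[Chem.Mol] = None,
    _battery: Optional[np.ndarray] = None,
) -> DescriptorVector:
    """Assemble the full descriptor vector for one coupling record.

    ``same_type_records`` must hold every record of this record's type in the
    molecule (including the record itself); it defaults to just the record,
    which is only correct when the record is the sole one of its type.
    """
    names = feature_names(record.coupling_type, mode)
    if same_type_records is None:
        same_type_records = [record]
    molecular = standard_molecular_descriptors(
        structure, graph, record, _mol=_mol, _battery=_battery
    )
    d = pair_distance(structure, record.atom_index_0, record.atom_index_1)
    if mode == "traditional":
        return DescriptorVector(names, np.array(molecular + [d]))
    values = molecular + [d]
    values += same_type_distance_descriptors(same_type_records, record, structure)
    values += midpoint_descriptors(structure, record)
    if record.coupling_type in _HH_TYPES:
        values += hh_replacement_descriptors(structure, graph, record, same_type_records)
    else:
        tail = target_atom_descriptors(structure, record)
        if record.coupling_type in _NH_TYPES:
            removed = TARGET_ATOM_NAMES.index(NH_REMOVED_NAME)
            tail = tail[:removed] + tail[removed + 1:]
        values += tail
    return DescriptorVector(names, np.array(values))


_META_COLUMNS = ["molecule_name", "atom_index_0", "atom_index_1", "type"]


def featurize_table(
    structures: Dict[str, MolecularStructure],
    couplings: CouplingTable,
    mode: str = "proposed",
    graphs: Optional[Dict[str, BondGraph]] = None,
) -> pd.DataFrame:
    """Featurize a single-type coupling table into a feature DataFrame.

    All records must share one coupling type.  The result carries the meta
    columns (molecule_name, atom indices, type), every descriptor column in
    the frozen order, and — when constants are present — a final ``y``
    column in Hz.  Per-molecule work (bond graph, toolkit molecule, the
    molecule-level descriptor battery) is computed once per molecule.
    """
    types = couplings.coupling_types
    if len(types) > 1:
        raise ValueError(f"featurize_table expects a single coupling type, got {types}")
    if len(couplings) == 0:
        return pd.DataFrame(columns=_META_COLUMNS)
    ctype = types[0]
    names = feature_names(ctype, mode)
    rows = np.empty((len(couplings), len(names)))
    by_mol = couplings.by_molecule()
    meta: List[tuple] = []
    y: List[Optional[float]] = []
    r = 0
    for mol_id, recs in by_mol.items():
        try:
            structure = structures[mol_id]
        except KeyError:
            raise KeyError(f"no structure for molecule {mol_id!r}") from None
        graph = graphs[mol_id] if graphs and mol_id in graphs else perceive_bonds(structure)
        mol = build_toolkit_mol(structure, graph)
        battery = _battery_values(mol)
        for rec in recs:
            vec = featurize(
                structure, graph, rec, mode=mode, same_type_records=recs,
                _mol=mol, _battery=battery,
            )
            rows[r] = vec.values
            meta.append((mol_id, rec.atom_index_0, rec.atom_index_1, ctype))
            y.append(rec.constant_hz)
            r += 1
    df = pd.DataFrame(rows, columns=list(names))
    for k, col in enumerate(_META_COLUMNS):
        df.insert(k, col, [m[k] for m in meta])
    if any(v is not None for v in y):
        df["y"] = [np.nan if v is None else v for v in y]
    return df


def variance_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.95,
    columns: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Near-constant-column filter: keep mask over the matrix's columns.

    A column is dropped iff its single most frequent value accounts for at
    least ``threshold`` of the rows.  Only the toolkit molecular-descriptor
    block is eligible for dropping (all other columns are always kept);
    ``columns`` overrides that eligible set.
    """
    if matrix.shape[0] == 0:
        raise ValueError("feature matrix must be nonempty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    eligible = set(MOLECULAR_DESCRIPTOR_NAMES) if columns is None else set(columns)
    n = matrix.shape[0]
    keep = {}
    for col in matrix.columns:
        if col in eligible:
            top = matrix[col].value_counts(dropna=False).iloc[0]
            keep[col] = bool(top < threshold * n)
        else:
            keep[col] = True
    return pd.Series(keep, index=matrix.columns)
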