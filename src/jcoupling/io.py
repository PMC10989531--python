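"""Readers and writers for the structure/coupling CSV dialect and XYZ files.

The CSV dialect follows the CHAMPS/Kaggle scalar-coupling layout: a per-atom
structure table (``molecule_name, atom_index, atom, x, y, z`` with coordinates
in Å) and a coupling table (``molecule_name, atom_index_0, atom_index_1, type``
plus an optional ``scalar_coupling_constant`` column in Hz).  This module also
houses the core record types used throughout the package.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "COUPLING_TYPES",
    "FormatError",
    "MolecularStructure",
    "CouplingRecord",
    "CouplingTable",
    "normalize_coupling_type",
    "read_structures_csv",
    "write_structures_csv",
    "read_couplings_csv",
    "write_couplings_csv",
    "read_xyz",
    "write_xyz",
    "write_predictions_csv",
]

#: Element symbols that may appear in a molecule.
ELEMENTS = ("C", "H", "N", "O", "F")

#: Canonical coupling-type spellings (hydrogen written second for
#: heteronuclear types, matching the usual nJ_XH notation).
COUPLING_TYPES = ("1JNH", "1JCH", "2JHH", "2JNH", "2JCH", "3JHH", "3JCH", "3JNH")

# The Kaggle files spell heteronuclear types with the hydrogen first
# (e.g. "1JHC"); both spellings normalize onto the canonical one.
_TYPE_NORMALIZATION = {t: t for t in COUPLING_TYPES}
_TYPE_NORMALIZATION.update(
    {f"{t[0]}JH{t[2]}": t for t in COUPLING_TYPES if t[3] == "H" and t[2] != "H"}
)


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def normalize_coupling_type(type_string: str) -> str:
    """Map a coupling-type spelling (canonical or Kaggle) onto the canonical one.

    Raises :class:`FormatError` for strings outside the eight-type taxonomy.
    """
    try:
        return _TYPE_NORMALIZATION[type_string.strip()]
    except KeyError:
        raise FormatError(
            f"unknown coupling type {type_string!r}; expected one of "
            f"{sorted(set(_TYPE_NORMALIZATION))}"
        ) from None


@dataclass(frozen=True)
class MolecularStructure:
    """One molecule: element symbols and Cartesian coordinates in Å.

    Atom indices are 0-based positions in ``elements``/``coords``.
    """

    molecule_id: str
    elements: tuple
    coords: np.ndarray  # shape (n_atoms, 3), Å

    def __post_init__(self):
        elements = tuple(self.elements)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(elements) != coords.shape[0] or len(elements) < 1:
            raise ValueError("elements and coords must have equal length >= 1")
        bad = set(elements) - set(ELEMENTS)
        if bad:
            raise FormatError(f"unknown element symbol(s) {sorted(bad)}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def element(self, index: int) -> str:
        return self.elements[index]


@dataclass(frozen=True)
class CouplingRecord:
    """One (H, partner) atom pair: the unit of prediction.

    ``atom_index_0`` is the hydrogen end; ``constant_hz`` is absent for
    prediction targets.
    """

    molecule_id: str
    atom_index_0: int
    atom_index_1: int
    coupling_type: str
    constant_hz: Optional[float] = None

    def __post_init__(self):
        if self.atom_index_0 == self.atom_index_1:
            raise ValueError("a coupling pair needs two distinct atoms")
        object.__setattr__(
            self, "coupling_type", normalize_coupling_type(self.coupling_type)
        )
        if self.constant_hz is not None and not math.isfinite(self.constant_hz):
            raise ValueError("coupling constant must be finite")

    @property
    def pair_key(self):
        i, j = self.atom_index_0, self.atom_index_1
        return (self.molecule_id, (i, j) if i < j else (j, i), self.coupling_type)

    def with_constant(self, value: float) -> "CouplingRecord":
        return replace(self, constant_hz=float(value))


@dataclass
class CouplingTable:
    """An ordered collection of coupling records, duplicate-free."""

    records: List[CouplingRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = rec.pair_key
            if key in seen:
                raise FormatError(f"duplicate coupling record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CouplingRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def coupling_types(self) -> List[str]:
        """Distinct types present, in canonical taxonomy order."""
        present = {r.coupling_type for r in self.records}
        return [t for t in COUPLING_TYPES if t in present]

    def by_type(self, coupling_type: str) -> "CouplingTable":
        t = normalize_coupling_type(coupling_type)
        return CouplingTable([r for r in self.records if r.coupling_type == t])

    def by_molecule(self) -> Dict[str, List[CouplingRecord]]:
        out: Dict[str, List[CouplingRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.molecule_id, []).append(rec)
        return out

    def molecule_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.molecule_id)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "molecule_name": [r.molecule_id for r in self.records],
                "atom_index_0": [r.atom_index_0 for r in self.records],
                "atom_index_1": [r.atom_index_1 for r in self.records],
                "type": [r.coupling_type for r in self.records],
            }
        )
        constants = [r.constant_hz for r in self.records]
        if any(c is not None for c in constants):
            df["scalar_coupling_constant"] = [
                np.nan if c is None else c for c in constants
            ]
        return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_structures_csv(path) -> Dict[str, MolecularStructure]:
    """Read a per-atom structure table into a map of molecule_id -> structure.

    Atoms are ordered by ``atom_index``, which must be contiguous from 0
    within each molecule.
    """
    df = pd.read_csv(path, dtype={"molecule_name": str, "atom": str})
    _require_columns(df, ("molecule_name", "atom_index", "atom", "x", "y", "z"), path)
    out: Dict[str, MolecularStructure] = {}
    if df.empty:
        return out
    try:
        df["atom_index"] = df["atom_index"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer atom_index ({exc})") from None
    for mol_id, grp in df.groupby("molecule_name", sort=False):
        grp = grp.sort_values("atom_index")
        idx = grp["atom_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(grp))):
            raise FormatError(
                f"{path}: molecule {mol_id!r} has non-contiguous atom_index values"
            )
        out[str(mol_id)] = MolecularStructure(
            molecule_id=str(mol_id),
            elements=tuple(grp["atom"]),
            coords=grp[["x", "y", "z"]].to_numpy(dtype=float),
        )
    return out


def write_structures_csv(structures: Dict[str, MolecularStructure], path) -> None:
    """Write structures in the per-atom CSV dialect (round-trips with the reader)."""
    rows = []
    for mol_id in structures:
        s = structures[mol_id]
        for i in range(s.n_atoms):
            x, y, z = s.coords[i]
            rows.append((s.molecule_id, i, s.elements[i], f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"))
    df = pd.DataFrame(rows, columns=["molecule_name", "atom_index", "atom", "x", "y", "z"])
    df.to_csv(path, index=False)


def read_couplings_csv(path) -> CouplingTable:
    """Read a coupling table; type strings are normalized to the canonical spelling."""
    df = pd.read_csv(path, dtype={"molecule_name": str, "type": str})
    _require_columns(df, ("molecule_name", "atom_index_0", "atom_index_1", "type"), path)
    has_constant = "scalar_coupling_constant" in df.columns
    records = []
    for row in df.itertuples(index=False):
        try:
            i0 = int(getattr(row, "atom_index_0"))
            i1 = int(getattr(row, "atom_index_1"))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-integer atom index ({exc})") from None
        constant = None
        if has_constant:
            value = getattr(row, "scalar_coupling_constant")
            constant = None if pd.isna(value) else float(value)
        records.append(
            CouplingRecord(
                molecule_id=str(getattr(row, "molecule_name")),
                atom_index_0=i0,
                atom_index_1=i1,
                coupling_type=str(getattr(row, "type")),
                constant_hz=constant,
            )
        )
    return CouplingTable(records)


def write_couplings_csv(table: CouplingTable, path) -> None:
    """Write a coupling table in the input dialect (constants to 6 decimals)."""
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6f")


def read_xyz(path) -> MolecularStructure:
    """Read a standard XYZ file; the molecule id is the filename stem."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{path}: first line must be the atom count") from None
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != n:
        raise FormatError(
            f"{path}: count line says {n} atoms but {len(atom_lines)} atom lines found"
        )
    elements, coords = [], []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        elements.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise FormatError(f"{path}: non-numeric coordinate in {ln!r}") from None
    stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return MolecularStructure(stem, tuple(elements), np.array(coords))


def write_xyz(structure: MolecularStructure, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(structure.elements, structure.coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_predictions_csv(table: CouplingTable, path) -> None:
    """Write predicted constants; every record must carry a value."""
    missing = [r.pair_key for r in table if r.constant_hz is None]
    if missing:
        raise ValueError(f"{len(missing)} record(s) missing a prediction, e.g. {missing[0]}")
    df = table.to_dataframe()
    if "scalar_coupling_constant" not in df.columns:  # empty table
        df["scalar_coupling_constant"] = pd.Series(dtype=float)
    df = df.rename(columns={"scalar_coupling_constant": "predicted_scalar_coupling_constant"})
    df.to_csv(path, index=False, float_format="%.6f")


def read_predictions_csv(path) -> CouplingTable:
    """Read back a predictions file written by :func:`write_predictions_csv`."""
    df = pd.read_csv(path, dtype={"molecule_name": str, "type": str})
    _require_columns(
        df,
        ("molecule_name", "atom_index_0", "atom_index_1", "type",
         "predicted_scalar_coupling_constant"),
        path,
    )
    records = [
        CouplingRecord(
            str(r.molecule_name), int(r.atom_index_0), int(r.atom_index_1),
            str(r.type), float(r.predicted_scalar_coupling_constant),
        )
        for r in df.itertuples(index=False)
    ]
    return CouplingTable(records)
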