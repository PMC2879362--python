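"""Molecular data model and file I/O.

Units are fixed package-wide: coordinates in Angstrom, partial charges in
elementary charge units, radii in Angstrom, energies in kcal/mol.  Protein
residue numbering is 1-based as in the source PDB file.

The readers cover the three plain-text formats the pipeline consumes:
PDB (ATOM/HETATM records) for proteins, PQR for charge/radius-annotated
solutes, and SDF V2000 (via RDKit) for ligand connection tables.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Molecule",
    "Complex",
    "ParseError",
    "ParameterError",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "write_pqr",
    "read_sdf",
    "write_sdf",
    "assign_parameters",
    "load_parameter_table",
]

# Periodic-table symbols accepted by the Atom invariant (the subset that can
# plausibly occur in protein/ligand/cofactor inputs plus common ions).
_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "I", "Xe", "Cs", "Ba", "W", "Pt", "Au", "Hg", "Pb",
}


class ParseError(ValueError):
    """Raised for malformed structure files; carries the offending line number."""


class ParameterError(ValueError):
    """Raised when parameter assignment cannot cover every atom."""


@dataclass
class Atom:
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    partial_charge: float | None = None  # elementary charges
    radius: float | None = None  # Angstrom
    name: str = ""
    residue_id: int | None = None
    lj_epsilon: float | None = None  # kcal/mol
    lj_sigma: float | None = None  # Angstrom

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("Atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("Atom position must be finite")
        if self.element not in _ELEMENTS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("Atom radius must be positive")


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    net_charge: float | None = None
    name: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index ({i},{j}) out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @coordinates.setter
    def coordinates(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(len(self.atoms), 3)
        for atom, row in zip(self.atoms, xyz):
            atom.position = row.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [0.0 if a.partial_charge is None else a.partial_charge for a in self.atoms]
        )

    @property
    def radii(self) -> np.ndarray:
        return np.array([np.nan if a.radius is None else a.radius for a in self.atoms])

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def check_net_charge(self, tol: float = 1e-6) -> None:
        """Verify the declared net charge matches the sum of partial charges."""
        if self.net_charge is None:
            return
        if abs(self.total_charge() - self.net_charge) > tol:
            raise ValueError(
                f"net_charge {self.net_charge} inconsistent with partial-charge "
                f"sum {self.total_charge():.6f}"
            )

    def copy(self) -> "Molecule":
        return copy.deepcopy(self)


@dataclass
class Complex:
    """A scored protein-ligand complex; the Ca(II) site is carried as a cofactor."""

    protein: Molecule
    ligand: Molecule
    cofactors: list[Molecule] = field(default_factory=list)

    @property
    def has_calcium(self) -> bool:
        return any(
            len(m) == 1 and m.atoms[0].element == "Ca" for m in self.cofactors
        )

    def receptor_atoms(self) -> list[Atom]:
        """Protein plus cofactor atoms — the environment the ligand interacts with."""
        atoms = list(self.protein.atoms)
        for m in self.cofactors:
            atoms.extend(m.atoms)
        return atoms


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    name = name.strip()
    if len(name) >= 2 and name[:2].capitalize() in _ELEMENTS and not name[0].isdigit():
        two = name[:2].capitalize()
        # Prefer two-letter symbols only for genuine two-letter elements
        if two in {"Cl", "Br", "Ca", "Na", "Mg", "Zn", "Fe", "Se", "Mn", "Cu"}:
            return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def read_pdb(path: str | Path) -> Molecule:
    """Read ATOM/HETATM records of a PDB file into a Molecule.

    Coordinates are taken from the fixed wwPDB v3.3 columns; the element
    column (77-78) is used when present, otherwise inferred from the atom
    name.  Charges and radii are left unassigned.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            line = raw.rstrip("\n")
            try:
                name = line[12:16].strip()
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                elem = line[76:78].strip().capitalize() if len(line) >= 77 else ""
                if not elem:
                    elem = _guess_element(name)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}: malformed {rec} record at line {lineno}: {exc}") from exc
            atoms.append(Atom(element=elem, position=(x, y, z), name=name, residue_id=resseq))
    if not atoms:
        raise ParseError(f"{path.name}: no atoms (empty ATOM/HETATM section)")
    return Molecule(atoms=atoms, name=path.stem)


def write_pdb(mol: Molecule, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(mol.atoms, start=1):
            resid = a.residue_id if a.residue_id is not None else 1
            fh.write(
                f"ATOM  {i:5d} {a.name[:4]:<4s} RES A{resid:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"  1.00  0.00          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> Molecule:
    """Read a whitespace-delimited PQR file (ATOM records with charge, radius)."""
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            parts = raw.split()
            # ATOM serial name resname [chain] resseq x y z charge radius
            if len(parts) < 10:
                raise ParseError(
                    f"{path.name}: PQR record at line {lineno} lacks charge/radius columns"
                )
            try:
                x, y, z, q, r = (float(v) for v in parts[-5:])
                name = parts[2]
                # residue number sits just before the coordinates
                resseq = int(parts[-6])
            except ValueError as exc:
                raise ParseError(f"{path.name}: malformed PQR record at line {lineno}: {exc}") from exc
            atoms.append(
                Atom(
                    element=_guess_element(name),
                    position=(x, y, z),
                    partial_charge=q,
                    radius=r,
                    name=name,
                    residue_id=resseq,
                )
            )
    if not atoms:
        raise ParseError(f"{path.name}: no atoms (empty ATOM/HETATM section)")
    mol = Molecule(atoms=atoms, name=path.stem)
    mol.net_charge = mol.total_charge()
    return mol


def write_pqr(mol: Molecule, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(mol.atoms, start=1):
            resid = a.residue_id if a.residue_id is not None else 1
            q = 0.0 if a.partial_charge is None else a.partial_charge
            r = 0.0 if a.radius is None else a.radius
            name = a.name or a.element
            fh.write(
                f"ATOM  {i:5d} {name[:4]:<4s} RES  {resid:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f} "
                f"{q:8.4f} {r:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# SDF (V2000) via RDKit
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> Molecule:
    """Read the first molecule of an SDF V2000 file (coordinates + bonds)."""
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    rdmol = next((m for m in supplier if m is not None), None)
    if rdmol is None:
        raise ParseError(f"{path.name}: no parsable molecule in SDF")
    conf = rdmol.GetConformer()
    atoms = []
    for idx, rdatom in enumerate(rdmol.GetAtoms()):
        pos = conf.GetAtomPosition(idx)
        atoms.append(
            Atom(
                element=rdatom.GetSymbol(),
                position=(pos.x, pos.y, pos.z),
                name=f"{rdatom.GetSymbol()}{idx + 1}",
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
        for b in rdmol.GetBonds()
    ]
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else path.stem
    return Molecule(atoms=atoms, bonds=bonds, name=name or path.stem)


def write_sdf(mol: Molecule, path: str | Path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, Chem.BondType.values.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(mol.atoms))
    for idx, a in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, Point3D(*map(float, a.position)))
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(m)


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def load_parameter_table(paramset: str = "default") -> pd.DataFrame:
    """Load the packaged element parameter table (radius, LJ, default charge)."""
    if paramset != "default":
        raise ParameterError(f"unknown parameter set {paramset!r}")
    with resources.files("pla2rank.data").joinpath("ff_parameters.csv").open() as fh:
        return pd.read_csv(fh).set_index("element")


def assign_parameters(mol: Molecule, paramset: str = "default") -> Molecule:
    """Populate radii, LJ parameters and missing charges from the element table.

    Already-populated fields (e.g. PQR charges/radii) are left untouched, so
    the operation is idempotent.  Returns a new Molecule.
    """
    table = load_parameter_table(paramset)
    out = mol.copy()
    missing = sorted(
        {a.element for a in out.atoms if a.element not in table.index}
    )
    if missing:
        raise ParameterError(
            f"no parameters for element(s) {', '.join(missing)} in set {paramset!r}"
        )
    for a in out.atoms:
        row = table.loc[a.element]
        if a.radius is None:
            a.radius = float(row["radius"])
        if a.partial_charge is None:
            a.partial_charge = float(row["default_charge"])
        if a.lj_epsilon is None:
            a.lj_epsilon = float(row["lj_epsilon"])
        if a.lj_sigma is None:
            a.lj_sigma = float(row["lj_sigma"])
    if out.net_charge is None:
        out.net_charge = out.total_charge()
    out.check_net_charge(tol=1e-6)
    return out
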