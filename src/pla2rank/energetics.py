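"""Surrogate molecular-mechanics energy terms.

The binding-balance ledger needs three molecular-mechanics quantities: the
intermolecular interaction energy E_int between ligand and receptor, the
intramolecular strain paid by each partner on binding (dE_lig, dE_prot), and
a local minimizer to define the relaxed free-state reference.  The force
field here is a transparent surrogate — Coulomb with a uniform interior
dielectric (default eps=4) plus Lennard-Jones 6-12 nonbonded terms, and
harmonic bond / harmonic angle / cosine torsion bonded terms.  Absolute
energies are NOT comparable to any published class-II force field; the
contract is the functional form and the ledger arithmetic built on it.

Conventions (documented to avoid factor-of-two drift):
    bond     E = k * (r - r0)**2          [k in kcal/mol/A^2, no 1/2]
    angle    E = k * (theta - theta0)**2  [theta in radians]
    torsion  E = (V/2) * (1 + cos(n*phi - phi0))   [V = barrier height]

Energies in kcal/mol, distances in Angstrom, charges in elementary units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, Complex, Molecule

__all__ = [
    "COULOMB_CONSTANT",
    "FFParams",
    "BondTerm",
    "AngleTerm",
    "TorsionTerm",
    "Topology",
    "EnergyReport",
    "interaction_energy",
    "internal_energy",
    "minimize",
    "strain_cost",
]

#: Coulomb conversion constant, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0637


@dataclass
class FFParams:
    """Force-field configuration shared by all energy routines."""

    dielectric_constant: float = 4.0
    dielectric_model: str = "constant"  # or "distance_dependent"
    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float | None = None  # Angstrom; None = no cutoff
    scale_14: float = 0.5  # scaling of 1-4 intramolecular nonbonded pairs

    def __post_init__(self):
        if self.dielectric_constant < 1:
            raise ValueError("dielectric_constant must be >= 1")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive if set")
        if self.dielectric_model not in ("constant", "distance_dependent"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")


@dataclass
class BondTerm:
    i: int
    j: int
    k: float  # kcal/mol/A^2
    r0: float  # A


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int
    force_k: float  # kcal/mol/rad^2
    theta0: float  # radians


@dataclass
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    barrier: float  # V, kcal/mol (peak-to-trough amplitude)
    n: int
    phi0: float = 0.0  # radians


@dataclass
class Topology:
    """Explicit bonded terms for a molecule (the surrogate has no atom typer)."""

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)

    def signature(self) -> tuple:
        return (
            tuple((b.i, b.j) for b in self.bonds),
            tuple((a.i, a.j, a.k) for a in self.angles),
            tuple((t.i, t.j, t.k, t.l) for t in self.torsions),
        )


@dataclass
class EnergyReport:
    e_total: float
    e_coulomb: float
    e_lj: float
    e_bonded: float
    gradient_max: float = float("nan")

    def __post_init__(self):
        assert abs(self.e_total - (self.e_coulomb + self.e_lj + self.e_bonded)) < 1e-6

    def to_dict(self) -> dict:
        return {
            "e_total": self.e_total,
            "e_coulomb": self.e_coulomb,
            "e_lj": self.e_lj,
            "e_bonded": self.e_bonded,
            "gradient_max": self.gradient_max,
        }


def _pair_arrays(atoms_a: list[Atom], atoms_b: list[Atom]):
    xa = np.array([a.position for a in atoms_a])
    xb = np.array([b.position for b in atoms_b])
    qa = np.array([0.0 if a.partial_charge is None else a.partial_charge for a in atoms_a])
    qb = np.array([0.0 if b.partial_charge is None else b.partial_charge for b in atoms_b])
    ea = np.array([0.0 if a.lj_epsilon is None else a.lj_epsilon for a in atoms_a])
    eb = np.array([0.0 if b.lj_epsilon is None else b.lj_epsilon for b in atoms_b])
    sa = np.array([0.0 if a.lj_sigma is None else a.lj_sigma for a in atoms_a])
    sb = np.array([0.0 if b.lj_sigma is None else b.lj_sigma for b in atoms_b])
    return xa, xb, qa, qb, ea, eb, sa, sb


def _nonbonded(xa, xb, qa, qb, ea, eb, sa, sb, ff: FFParams, mask=None):
    """Vectorised Coulomb + LJ over all cross pairs; mask selects pairs."""
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    if mask is None:
        mask = np.ones_like(r, dtype=float)
    active = mask > 0
    if np.any(active & (r < 1e-6)):
        raise ValueError("overlapping atoms (pair distance < 1e-6 A)")
    with np.errstate(divide="ignore", invalid="ignore"):
        if ff.dielectric_model == "constant":
            e_coul = ff.coulomb_constant * qa[:, None] * qb[None, :] / (
                ff.dielectric_constant * r
            )
        else:  # distance-dependent eps(r) = eps * r
            e_coul = ff.coulomb_constant * qa[:, None] * qb[None, :] / (
                ff.dielectric_constant * r**2
            )
        # Lorentz-Berthelot combination
        eps_ij = np.sqrt(ea[:, None] * eb[None, :])
        sig_ij = 0.5 * (sa[:, None] + sb[None, :])
        sr6 = (sig_ij / r) ** 6
        e_lj = 4.0 * eps_ij * (sr6**2 - sr6)
    e_coul = np.where(active, e_coul, 0.0)
    e_lj = np.where(active, e_lj, 0.0)
    if ff.cutoff is not None:
        beyond = r > ff.cutoff
        e_coul = np.where(beyond, 0.0, e_coul)
        e_lj = np.where(beyond, 0.0, e_lj)
    return float((e_coul * mask).sum()), float((e_lj * mask).sum())


def interaction_energy(cplx: Complex, ff: FFParams | None = None) -> float:
    """Ligand-receptor nonbonded interaction energy E_int (kcal/mol).

    Sums Coulomb and Lennard-Jones terms over every (ligand atom, protein or
    cofactor atom) pair; no intramolecular terms enter.  Symmetric in the
    roles of the two partners and tends to zero at large separation.
    """
    ff = ff or FFParams()
    lig = cplx.ligand.atoms
    rec = cplx.receptor_atoms()
    for a in itertools.chain(lig, rec):
        if a.lj_sigma is None or a.partial_charge is None:
            raise ValueError("all atoms must be parameterized before scoring")
    e_coul, e_lj = _nonbonded(*_pair_arrays(lig, rec), ff)
    return e_coul + e_lj


def _exclusion_mask(n: int, bonds: list[tuple[int, int, int]], scale_14: float) -> np.ndarray:
    """Intramolecular pair mask: 1-2 and 1-3 excluded, 1-4 scaled, self excluded."""
    adj = [set() for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    mask = np.triu(np.ones((n, n)), k=1)
    for i in range(n):
        for j in adj[i]:
            mask[min(i, j), max(i, j)] = 0.0  # 1-2
        for j in adj[i]:
            for k in adj[j]:
                if k != i:
                    mask[min(i, k), max(i, k)] = 0.0  # 1-3
    # 1-4: neighbours at 3 bonds that are not already excluded
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k == i:
                    continue
                for l in adj[k]:
                    if l in (i, j):
                        continue
                    a, b = min(i, l), max(i, l)
                    if mask[a, b] == 1.0:
                        mask[a, b] = scale_14
    return mask


def _bonded_energy(xyz: np.ndarray, topo: Topology) -> float:
    e = 0.0
    for b in topo.bonds:
        r = np.linalg.norm(xyz[b.i] - xyz[b.j])
        e += b.k * (r - b.r0) ** 2
    for a in topo.angles:
        v1 = xyz[a.i] - xyz[a.j]
        v2 = xyz[a.k] - xyz[a.j]
        cos_t = np.clip(
            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
        )
        e += a.force_k * (np.arccos(cos_t) - a.theta0) ** 2
    for t in topo.torsions:
        e += (t.barrier / 2.0) * (1.0 + np.cos(t.n * _dihedral(xyz, t) - t.phi0))
    return e


def _dihedral(xyz: np.ndarray, t: TorsionTerm) -> float:
    b1 = xyz[t.j] - xyz[t.i]
    b2 = xyz[t.k] - xyz[t.j]
    b3 = xyz[t.l] - xyz[t.k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def _energy_of_coords(xyz: np.ndarray, mol: Molecule, topo: Topology, ff: FFParams):
    """(e_coulomb, e_lj, e_bonded) at the given coordinates."""
    atoms = mol.atoms
    n = len(atoms)
    qa = np.array([0.0 if a.partial_charge is None else a.partial_charge for a in atoms])
    ea = np.array([0.0 if a.lj_epsilon is None else a.lj_epsilon for a in atoms])
    sa = np.array([0.0 if a.lj_sigma is None else a.lj_sigma for a in atoms])
    mask = _exclusion_mask(n, mol.bonds, ff.scale_14)
    e_coul, e_lj = _nonbonded(xyz, xyz, qa, qa, ea, ea, sa, sa, ff, mask=mask)
    return e_coul, e_lj, _bonded_energy(xyz, topo)


def _gradient(xyz: np.ndarray, mol: Molecule, topo: Topology, ff: FFParams,
              h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient; systems here are desk-scale."""
    g = np.zeros_like(xyz)
    for i in range(xyz.shape[0]):
        for d in range(3):
            xp = xyz.copy()
            xp[i, d] += h
            xm = xyz.copy()
            xm[i, d] -= h
            ep = sum(_energy_of_coords(xp, mol, topo, ff))
            em = sum(_energy_of_coords(xm, mol, topo, ff))
            g[i, d] = (ep - em) / (2 * h)
    return g


def internal_energy(mol: Molecule, ff: FFParams | None = None,
                    topology: Topology | None = None,
                    with_gradient: bool = False) -> EnergyReport:
    """Intramolecular energy: bonded terms plus nonbonded with 1-2/1-3
    exclusions and scaled 1-4 pairs."""
    ff = ff or FFParams()
    topo = topology or Topology()
    xyz = mol.coordinates
    e_coul, e_lj, e_bonded = _energy_of_coords(xyz, mol, topo, ff)
    gmax = float("nan")
    if with_gradient:
        gmax = float(np.abs(_gradient(xyz, mol, topo, ff)).max()) if len(mol) else 0.0
    return EnergyReport(
        e_total=e_coul + e_lj + e_bonded,
        e_coulomb=e_coul,
        e_lj=e_lj,
        e_bonded=e_bonded,
        gradient_max=gmax,
    )


def minimize(mol: Molecule, ff: FFParams | None = None,
             topology: Topology | None = None,
             tol: float = 0.01, max_steps: int = 5000) -> Molecule:
    """Steepest descent with Armijo backtracking.

    Energy is non-increasing across accepted steps by construction.
    Terminates when the max gradient component falls below `tol`
    (kcal/mol/A) or after `max_steps`, in which case the returned molecule
    carries ``converged=False`` in its ``minimization_info`` attribute.
    """
    ff = ff or FFParams()
    topo = topology or Topology()
    xyz = mol.coordinates
    e = sum(_energy_of_coords(xyz, mol, topo, ff))
    step = 0.05
    converged = False
    n_steps = 0
    for n_steps in range(1, max_steps + 1):
        g = _gradient(xyz, mol, topo, ff)
        gmax = float(np.abs(g).max()) if g.size else 0.0
        if gmax <= tol:
            converged = True
            break
        # Backtracking line search along -g
        accepted = False
        alpha = step
        for _ in range(40):
            trial = xyz - alpha * g
            try:
                e_trial = sum(_energy_of_coords(trial, mol, topo, ff))
            except ValueError:
                e_trial = np.inf
            if np.isnan(e_trial):
                raise ValueError(f"NaN energy during line search at step {n_steps}")
            if e_trial <= e - 1e-4 * alpha * float((g * g).sum()):
                xyz, e = trial, e_trial
                step = min(alpha * 2.0, 0.5)
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # gradient direction yields no decrease at machine scale: stop
            converged = gmax <= tol
            break
    else:
        n_steps = max_steps
    out = mol.copy()
    out.coordinates = xyz
    out.minimization_info = {  # type: ignore[attr-defined]
        "converged": converged,
        "steps": n_steps,
        "final_energy": float(e),
    }
    if not converged:
        import warnings

        warnings.warn("minimize: gradient tolerance not reached", stacklevel=2)
    return out


def strain_cost(bound_geometry: Molecule, free_reference: Molecule,
                ff: FFParams | None = None,
                topology: Topology | None = None,
                reminimize_reference: bool = True,
                tol: float = 0.01, max_steps: int = 5000) -> float:
    """Conformational strain: internal energy of the bound geometry minus
    that of the (minimized) free reference on the same surface.

    Nonnegative (to numerical tolerance) whenever the reference is at the
    minimum of the shared energy surface.
    """
    ff = ff or FFParams()
    if len(bound_geometry) != len(free_reference) or [
        (i, j) for i, j, _ in bound_geometry.bonds
    ] != [(i, j) for i, j, _ in free_reference.bonds]:
        raise ValueError("bound and free molecules must share the same topology")
    ref = free_reference
    if reminimize_reference:
        ref = minimize(free_reference, ff, topology, tol=tol, max_steps=max_steps)
    e_bound = internal_energy(bound_geometry, ff, topology).e_total
    e_free = internal_energy(ref, ff, topology).e_total
    return e_bound - e_free
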