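"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pla2rank.structures import Atom, Complex, Molecule


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def kendall_tau_b_oracle(x, y):
    """Brute-force tie-corrected Kendall tau-b by pair enumeration."""
    n = len(x)
    conc = disc = tx = ty = txy = 0
    for a in range(n):
        for b in range(a + 1, n):
            sx = int(x[a] > x[b]) - int(x[a] < x[b])
            sy = int(y[a] > y[b]) - int(y[a] < y[b])
            if sx == 0 and sy == 0:
                txy += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    n1 = tx + txy
    n2 = ty + txy
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    tau = (conc - disc) / denom if denom > 0 else np.nan
    return tau, conc, disc, n0 - conc - disc


def pairwise_energy_oracle(cplx: Complex, eps: float = 4.0) -> float:
    """O(n^2) Coulomb + LJ sum over ligand x (protein + cofactor) pairs."""
    kc = 332.0637
    total = 0.0
    for la in cplx.ligand.atoms:
        for ra in cplx.receptor_atoms():
            r = float(np.linalg.norm(la.position - ra.position))
            total += kc * la.partial_charge * ra.partial_charge / (eps * r)
            eij = np.sqrt(la.lj_epsilon * ra.lj_epsilon)
            sij = 0.5 * (la.lj_sigma + ra.lj_sigma)
            total += 4.0 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
    return total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def energy_table():
    from pla2rank.scoring import load_energy_table

    return load_energy_table()


@pytest.fixture(scope="session")
def inhibition_table():
    from pla2rank.scoring import load_inhibition_table

    return load_inhibition_table()


@pytest.fixture
def unit_charge_pair():
    """+1/-1 point charges 3.32 A apart with LJ switched off."""
    a1 = Atom(element="Na", position=(0.0, 0.0, 0.0), partial_charge=1.0,
              radius=1.0, lj_epsilon=0.0, lj_sigma=1.0)
    a2 = Atom(element="Cl", position=(3.32, 0.0, 0.0), partial_charge=-1.0,
              radius=1.0, lj_epsilon=0.0, lj_sigma=1.0)
    return Complex(protein=Molecule(atoms=[a1], name="p"),
                   ligand=Molecule(atoms=[a2], name="l"))


def make_poly_ala(n_residues: int = 50) -> Molecule:
    """Synthetic poly-alanine backbone (N, CA, C, O, CB per residue)."""
    atoms = []
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
    offsets = np.array([
        [0.0, 0.0, 0.0], [1.45, 0.0, 0.0], [2.2, 1.2, 0.0],
        [3.4, 1.2, 0.3], [1.9, -1.3, 0.8],
    ])
    for res in range(1, n_residues + 1):
        base = np.array([res * 3.8, 0.0, 0.0])
        for (name, elem), off in zip(names, offsets):
            atoms.append(Atom(element=elem, position=base + off,
                              name=name, residue_id=res))
    return Molecule(atoms=atoms, name="poly-ala")


@pytest.fixture
def poly_ala():
    return make_poly_ala(50)
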