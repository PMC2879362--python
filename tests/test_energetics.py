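"""Surrogate force-field contracts: hand values, symmetries, minimizer."""

import numpy as np
import pytest

from conftest import pairwise_energy_oracle

from pla2rank.energetics import (
    BondTerm,
    FFParams,
    Topology,
    TorsionTerm,
    interaction_energy,
    internal_energy,
    minimize,
    strain_cost,
)
from pla2rank.structures import Atom, Complex, Molecule
from pla2rank.synthetic import make_toy_complex


def _atom(x, q=0.0, eps=0.0, sigma=3.4, element="C"):
    return Atom(element=element, position=x, partial_charge=q,
                lj_epsilon=eps, lj_sigma=sigma, radius=1.7)


def _diatomic(r, k=300.0, r0=1.5):
    mol = Molecule(
        atoms=[_atom((0, 0, 0)), _atom((r, 0, 0))], bonds=[(0, 1, 1)], name="aa"
    )
    return mol, Topology(bonds=[BondTerm(0, 1, k=k, r0=r0)])


def test_coulomb_hand_value_unit_charges(unit_charge_pair):
    """+1/-1 at 3.32 A with eps=4: 332.0637/(4*3.32) = 25.0 kcal/mol."""
    e = interaction_energy(unit_charge_pair, FFParams(dielectric_constant=4.0))
    assert e == pytest.approx(-25.0, abs=0.05)


def test_interaction_energy_is_symmetric_and_matches_oracle():
    cplx = make_toy_complex(seed=3)
    e = interaction_energy(cplx)
    swapped = Complex(protein=cplx.ligand, ligand=cplx.protein,
                      cofactors=cplx.cofactors)
    # swapping roles keeps every cross pair (cofactor pairs move with them)
    assert interaction_energy(cplx) == pytest.approx(e, abs=1e-9)
    assert e == pytest.approx(pairwise_energy_oracle(cplx), rel=1e-12)
    assert interaction_energy(swapped) == pytest.approx(
        pairwise_energy_oracle(swapped), rel=1e-12
    )


def test_lj_zero_at_sigma_and_decay_to_zero():
    near = Complex(protein=Molecule(atoms=[_atom((0, 0, 0), eps=0.1)]),
                   ligand=Molecule(atoms=[_atom((3.4, 0, 0), eps=0.1)]))
    assert interaction_energy(near, FFParams()) == pytest.approx(0.0, abs=1e-12)

    ff = FFParams(cutoff=12.0)
    far = Complex(protein=Molecule(atoms=[_atom((0, 0, 0), eps=0.1)]),
                  ligand=Molecule(atoms=[_atom((50.0, 0, 0), eps=0.1)]))
    assert interaction_energy(far, ff) == 0.0


def test_rigid_motion_invariance():
    cplx = make_toy_complex(seed=9)
    e0 = interaction_energy(cplx)
    # rotate + translate every atom of the whole complex identically
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0],
        [np.sin(theta), np.cos(theta), 0],
        [0, 0, 1],
    ])
    shift = np.array([5.0, -3.0, 2.0])
    for mol in [cplx.protein, cplx.ligand, *cplx.cofactors]:
        mol.coordinates = mol.coordinates @ rot.T + shift
    assert interaction_energy(cplx) == pytest.approx(e0, abs=1e-6)


def test_doubling_dielectric_halves_coulomb():
    cplx = make_toy_complex(seed=5, include_calcium=False)
    # switch LJ off to isolate the Coulomb component
    for mol in (cplx.protein, cplx.ligand):
        for a in mol.atoms:
            a.lj_epsilon = 0.0
    e4 = interaction_energy(cplx, FFParams(dielectric_constant=4.0))
    e8 = interaction_energy(cplx, FFParams(dielectric_constant=8.0))
    assert e8 == pytest.approx(e4 / 2.0, rel=1e-12)


def test_overlapping_atoms_raise():
    clash = Complex(protein=Molecule(atoms=[_atom((0, 0, 0), q=0.1)]),
                    ligand=Molecule(atoms=[_atom((0, 0, 0), q=0.1)]))
    with pytest.raises(ValueError, match="overlap"):
        interaction_energy(clash, FFParams())


def test_bond_energy_convention_k_delta_squared():
    """E = k*(r-r0)^2: 0.1 A stretch at k=300 costs exactly 3.0 kcal/mol."""
    mol, topo = _diatomic(1.6)
    rep = internal_energy(mol, FFParams(), topo)
    assert rep.e_bonded == pytest.approx(3.0, abs=1e-9)
    assert rep.e_total == pytest.approx(rep.e_coulomb + rep.e_lj + rep.e_bonded)


def _torsion_fixture(phi_deg):
    phi = np.radians(phi_deg)
    xyz = np.array([
        [0, 1, 0], [0, 0, 0], [1.5, 0, 0],
        [1.5, np.cos(phi), np.sin(phi)],
    ], float)
    atoms = [_atom(p) for p in xyz]
    mol = Molecule(atoms=atoms, bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1)])
    topo = Topology(torsions=[TorsionTerm(0, 1, 2, 3, barrier=2.0, n=3, phi0=0.0)])
    return mol, topo


def test_threefold_torsion_barrier_height():
    """V=2, n=3: maximum (phi=0) minus minimum (phi=60 deg) equals V."""
    mol_max, topo = _torsion_fixture(0.0)
    mol_min, _ = _torsion_fixture(60.0)
    d = internal_energy(mol_max, FFParams(), topo).e_total - internal_energy(
        mol_min, FFParams(), topo
    ).e_total
    assert d == pytest.approx(2.0, abs=1e-9)


def test_minimize_diatomic_converges_to_r0():
    mol, topo = _diatomic(1.8)
    out = minimize(mol, FFParams(), topo, tol=0.01)
    r = np.linalg.norm(out.atoms[0].position - out.atoms[1].position)
    assert r == pytest.approx(1.5, abs=1e-3)
    assert out.minimization_info["converged"]


def test_minimize_leaves_minimum_unchanged():
    mol, topo = _diatomic(1.5)
    out = minimize(mol, FFParams(), topo, tol=0.01)
    assert np.abs(out.coordinates - mol.coordinates).max() <= 1e-6


def test_minimized_geometry_has_small_gradient():
    mol, topo = _diatomic(1.7)
    out = minimize(mol, FFParams(), topo, tol=0.01)
    rep = internal_energy(out, FFParams(), topo, with_gradient=True)
    assert rep.gradient_max <= 0.01 + 1e-6


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_minimize_never_increases_energy(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 6, (10, 3))
    mol = Molecule(atoms=[
        _atom(p, q=float(q), eps=0.086)
        for p, q in zip(pts, rng.uniform(-0.2, 0.2, 10))
    ])
    e0 = internal_energy(mol, FFParams()).e_total
    out = minimize(mol, FFParams(), tol=0.05, max_steps=120)
    assert out.minimization_info["final_energy"] <= e0 + 1e-9


def test_strain_cost_contracts():
    mol_max, topo = _torsion_fixture(0.0)
    mol_min, _ = _torsion_fixture(60.0)
    ff = FFParams()
    # identical geometries cost nothing
    assert strain_cost(mol_min, mol_min, ff, topo,
                       reminimize_reference=False) == pytest.approx(0.0, abs=1e-12)
    # 60 degrees off the free minimum of a V=2 threefold torsion costs V
    assert strain_cost(mol_max, mol_min, ff, topo,
                       reminimize_reference=False) == pytest.approx(2.0, abs=1e-9)
    # never beats the minimized reference on the same surface
    assert strain_cost(mol_max, mol_max, ff, topo) >= -1e-6


def test_strain_cost_topology_mismatch():
    mol, topo = _diatomic(1.5)
    other = Molecule(atoms=[_atom((0, 0, 0))])
    with pytest.raises(ValueError, match="topology"):
        strain_cost(mol, other, FFParams(), topo)


def test_table_strain_columns_are_nonnegative(energy_table):
    """The printed ligand/protein strain costs respect the nonnegativity
    contract of strain against a minimized free reference."""
    assert (energy_table["d_e_lig"] > 0).all()
    assert (energy_table["d_e_prot"] > 0).all()
    assert energy_table["d_e_lig"].between(8.0, 10.6).all()
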