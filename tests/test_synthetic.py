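"""Synthetic generators: reproducibility and simulate -> reduce consistency."""

import numpy as np
import pytest

from conftest import pairwise_energy_oracle

from pla2rank.assays import DoseResponse, fit_ic50, fold_induction, initial_rate, percent_activity
from pla2rank.energetics import interaction_energy
from pla2rank.synthetic import (
    MEDIA,
    GeneratorConfig,
    make_born_ion,
    make_toy_complex,
    simulate_cell_plate,
    simulate_kinetics,
)


def test_toy_complex_seed_reproducibility_and_geometry():
    a = make_toy_complex(seed=42)
    b = make_toy_complex(seed=42)
    np.testing.assert_array_equal(a.protein.coordinates, b.protein.coordinates)
    np.testing.assert_array_equal(a.ligand.charges, b.ligand.charges)
    c = make_toy_complex(seed=43)
    assert not np.array_equal(a.protein.coordinates, c.protein.coordinates)

    # no overlapping pairs anywhere in the complex
    all_xyz = np.vstack([a.protein.coordinates, a.ligand.coordinates]
                        + [m.coordinates for m in a.cofactors])
    d = np.linalg.norm(all_xyz[:, None] - all_xyz[None], axis=-1)
    assert d[np.triu_indices_from(d, k=1)].min() > 1.5


def test_toy_complex_energy_matches_pair_oracle():
    cplx = make_toy_complex(seed=7)
    assert interaction_energy(cplx) == pytest.approx(
        pairwise_energy_oracle(cplx), rel=1e-12)


def test_toy_complex_charge_conventions():
    cplx = make_toy_complex(seed=1)
    assert cplx.ligand.total_charge() == pytest.approx(-1.0, abs=1e-9)
    assert cplx.protein.total_charge() == pytest.approx(0.0, abs=1e-9)
    assert cplx.has_calcium
    neutral = make_toy_complex(seed=1, ligand_net_charge=0.0, include_calcium=False)
    assert neutral.ligand.total_charge() == pytest.approx(0.0, abs=1e-9)
    assert not neutral.has_calcium

    zero_q = make_toy_complex(seed=1, ligand_net_charge=0.0)
    for mol in (zero_q.protein, zero_q.ligand):
        for atom in mol.atoms:
            atom.partial_charge = 0.0
    zero_q.cofactors = []
    e = interaction_energy(zero_q)
    assert e == pytest.approx(pairwise_energy_oracle(zero_q), rel=1e-12)  # pure LJ


def test_born_ion_metadata():
    ion = make_born_ion(1.0, 2.0)
    assert len(ion) == 1
    assert ion.atoms[0].partial_charge == 1.0
    assert ion.atoms[0].radius == 2.0
    assert ion.born_reference["eps_in_1_eps_out_80"] == pytest.approx(-81.98, abs=0.01)
    null = make_born_ion(0.0, 2.0)
    assert null.born_reference["eps_in_1_eps_out_80"] == 0.0


def test_kinetics_noise_free_slopes_follow_logistic():
    cfg = GeneratorConfig(seed=0, kinetic_noise_sd=0.0)
    traces = simulate_kinetics(cfg, true_ic50=1.0, concentrations=[1.0])
    control, at_ic50 = traces
    r0 = initial_rate(control)
    assert r0 == pytest.approx(12.0, abs=1e-9)  # zero inhibitor: control slope
    assert percent_activity(initial_rate(at_ic50), r0) == pytest.approx(50.0, abs=1e-9)


def test_kinetics_to_ic50_recovery():
    cfg = GeneratorConfig(seed=20, kinetic_noise_sd=0.5)
    truth = 0.62
    concs = np.logspace(-2, 1.5, 8)
    acts = []
    for rep in range(3):
        traces = simulate_kinetics(
            GeneratorConfig(seed=cfg.seed + rep, kinetic_noise_sd=0.5), truth, concs)
        r0 = initial_rate(traces[0])
        acts.append([percent_activity(initial_rate(t), r0) for t in traces[1:]])
    fit = fit_ic50(DoseResponse(concentrations=concs,
                                percent_activity=np.mean(acts, axis=0)))
    assert fit.ic50 == pytest.approx(truth, rel=0.15)


def test_plate_seed_reproducibility():
    a = simulate_cell_plate(GeneratorConfig(seed=9), n_replicates=3)
    b = simulate_cell_plate(GeneratorConfig(seed=9), n_replicates=3)
    assert [(r.condition, r.medium, r.pge2, r.nitrite) for r in a] == [
        (r.condition, r.medium, r.pge2, r.nitrite) for r in b]


def test_plate_noise_free_folds_are_exact():
    cfg = GeneratorConfig(seed=0, noise_cv=0.0)
    recs = simulate_cell_plate(cfg, n_replicates=2)
    for medium in MEDIA:
        unt = np.mean([r.pge2 / r.protein for r in recs
                       if r.medium == medium and r.condition == "untreated"])
        il = np.mean([r.pge2 / r.protein for r in recs
                      if r.medium == medium and r.condition == "IL1b"])
        assert fold_induction(il, unt) == pytest.approx(cfg.pge2_folds[medium], abs=1e-9)


def test_plate_top_dose_returns_toward_control():
    """With full inhibition configured, the top dose brings PGE2 back to the
    untreated level, so %inhibition approaches 100*(1 - 1/fold)."""
    cfg = GeneratorConfig(seed=0, noise_cv=0.0)
    cfg.inhibition_emax["DMEM+0.1%BSA"] = 1.0
    cfg.inhibition_ec50_um["DMEM+0.1%BSA"] = 1e-9  # saturating at every dose
    recs = simulate_cell_plate(cfg, n_replicates=1)
    med = "DMEM+0.1%BSA"
    il = np.mean([r.pge2 for r in recs if r.medium == med and r.condition == "IL1b"])
    top = max(r.c8_dose for r in recs if r.medium == med)
    treated = np.mean([r.pge2 for r in recs
                       if r.medium == med and r.condition == "IL1b+C8"
                       and r.c8_dose == top])
    from pla2rank.assays import percent_inhibition

    fold = cfg.pge2_folds[med]
    assert percent_inhibition(treated, il) == pytest.approx(
        100.0 * (1.0 - 1.0 / fold), abs=1e-6)
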