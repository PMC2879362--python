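"""Assay reductions: rates, IC50 fitting, cellular statistics."""

import numpy as np
import pytest

from pla2rank.assays import (
    CellAssayRecord,
    DoseResponse,
    KineticTrace,
    densitometry_ratio,
    fit_ic50,
    fold_induction,
    four_pl,
    griess_quantify,
    initial_rate,
    mtt_viability,
    normalize_per_protein,
    percent_activity,
    percent_inhibition,
)


def _trace(slope_per_min, noise_sd=0.0, seed=0, n=13):
    t = np.linspace(0.0, 60.0, n)
    f = 5.0 + slope_per_min * t / 60.0
    if noise_sd:
        f = f + np.random.default_rng(seed).normal(0, noise_sd, n)
    return KineticTrace(times=t, fluorescence=f)


def test_initial_rate_exact_and_noisy():
    assert initial_rate(_trace(12.0)) == pytest.approx(12.0, abs=1e-9)
    assert initial_rate(_trace(12.0, noise_sd=0.5, seed=1)) == pytest.approx(12.0, rel=0.05)


def test_initial_rate_sign_passthrough():
    assert initial_rate(_trace(-4.0)) == pytest.approx(-4.0, abs=1e-9)


def test_initial_rate_needs_five_points():
    t = KineticTrace(times=np.array([0, 10, 20, 30, 40.0]),
                     fluorescence=np.zeros(5))
    with pytest.raises(ValueError, match="5 points"):
        initial_rate(t, window=(0.0, 25.0))
    with pytest.raises(ValueError, match="first minute"):
        KineticTrace(times=np.array([0.0, 30.0, 61.0, 62.0, 63.0]),
                     fluorescence=np.zeros(5))


def test_percent_activity():
    assert percent_activity(6.0, 6.0) == 100.0
    assert percent_activity(3.0, 6.0) == 50.0
    assert percent_activity(0.0, 6.0) == 0.0
    with pytest.raises(ValueError):
        percent_activity(1.0, 0.0)


@pytest.mark.parametrize("truth", np.logspace(-2, 2, 20))
def test_fit_ic50_noise_free_recovery(truth):
    """Noise-free 4PL data anywhere in [0.01, 100] uM recovers the truth to
    1e-6 relative error."""
    c = np.logspace(np.log10(truth) - 1.5, np.log10(truth) + 1.5, 9)
    fit = fit_ic50(DoseResponse(concentrations=c,
                                percent_activity=four_pl(c, truth, 1.0)))
    assert fit.ic50 == pytest.approx(truth, rel=1e-6)
    assert fit.hill == pytest.approx(1.0, rel=1e-4)


def test_fit_ic50_censors_without_crossing():
    """Activities staying above 90% up to the top tested concentration give a
    censored '>max' result, never a numeric IC50 beyond the tested range."""
    dr = DoseResponse(concentrations=np.array([1.0, 10.0, 50.0, 100.0]),
                      percent_activity=np.array([99.0, 98.0, 95.0, 92.0]))
    fit = fit_ic50(dr)
    assert fit.is_censored
    assert fit.censored_bound == 100.0
    assert str(fit) == ">100 uM"


def test_fit_ic50_noisy_recovery_within_fifteen_percent():
    """Truth 0.62 uM, 3 replicates, 5% noise, fixed seed: recovered within 15%."""
    truth = 0.62
    concs = np.logspace(-2, 1.5, 8)
    rng = np.random.default_rng(0)
    reps = [four_pl(concs, truth, 1.0) + rng.normal(0, 5.0, concs.size)
            for _ in range(3)]
    fit = fit_ic50(DoseResponse(concentrations=concs,
                                percent_activity=np.mean(reps, axis=0)))
    assert fit.ic50 == pytest.approx(truth, rel=0.15)


def test_percent_inhibition_formula():
    assert percent_inhibition(100.0, 100.0) == 0.0
    assert percent_inhibition(0.0, 100.0) == 100.0
    assert percent_inhibition(35.0, 100.0) == pytest.approx(65.0)
    with pytest.raises(ValueError):
        percent_inhibition(1.0, 0.0)


def test_fold_induction_and_inhibition_duality():
    assert fold_induction(23.3, 1.0) == pytest.approx(23.3)
    assert fold_induction(7.0, 7.0) == 1.0
    # zero inhibition iff the treated/control fold ratio is 1
    for treated, control in [(5.0, 5.0), (12.0, 4.0)]:
        inh = percent_inhibition(treated, control)
        fold = fold_induction(treated, control)
        assert (abs(inh) < 1e-12) == (abs(fold - 1.0) < 1e-12)


def _mtt(a570, a690):
    return CellAssayRecord(condition="IL1b", medium="DMEM",
                           absorbance_570=a570, absorbance_690=a690)


def test_mtt_viability():
    ref = [_mtt(0.9, 0.2)]
    assert mtt_viability([_mtt(0.9, 0.2)], ref) == pytest.approx(100.0)
    assert mtt_viability([_mtt(0.8, 0.1)], ref) == pytest.approx(100.0)  # 0.7/0.7
    assert mtt_viability([_mtt(0.2, 0.2)], ref) == pytest.approx(0.0)


def test_griess_calibration():
    standards = [(0.0, 0.010), (10.0, 0.110), (20.0, 0.210)]
    conc, info = griess_quantify(standards, [0.110, 0.010, 0.005])
    assert conc[0] == pytest.approx(10.0, abs=1e-9)
    assert conc[1] == pytest.approx(0.0, abs=1e-9)
    assert conc[2] == 0.0 and info["clamped"][2]  # negative prediction clamped

    rng = np.random.default_rng(3)
    c = np.linspace(0, 50, 8)
    a = 0.01 * c + 0.02 + rng.normal(0, 0.002, 8)
    conc, info = griess_quantify(list(zip(c, a)), [0.01 * 25.0 + 0.02])
    assert conc[0] == pytest.approx(25.0, rel=0.03)

    with pytest.raises(ValueError, match="monotone"):
        griess_quantify([(0.0, 0.1), (10.0, 0.05), (20.0, 0.2)], [0.1])


def test_normalization_and_densitometry():
    assert normalize_per_protein(100.0, 10.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        normalize_per_protein(10.0, 0.0)

    ratios = densitometry_ratio(np.array([2.0, 4.0]), np.array([1.0, 1.0]),
                                reference_index=0)
    assert ratios[0] == pytest.approx(1.0)
    assert ratios[1] == pytest.approx(2.0)  # doubled COX-1, constant COX-2
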