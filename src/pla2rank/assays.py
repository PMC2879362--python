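"""Reduction of enzymatic and cellular assay observations to summary statistics.

Covers the fluorimetric PLA2 kinetics (initial rate over the first minute
after CaCl2 addition, percent activity versus the uninhibited control,
four-parameter-logistic IC50 with censoring), and the cellular readouts:
percent inhibition, fold induction, MTT viability, Griess nitrite
calibration, per-protein normalization and densitometry ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "DoseResponse",
    "InhibitionRecord",
    "CellAssayRecord",
    "IC50Fit",
    "initial_rate",
    "percent_activity",
    "fit_ic50",
    "percent_inhibition",
    "fold_induction",
    "mtt_viability",
    "griess_quantify",
    "normalize_per_protein",
    "densitometry_ratio",
    "four_pl",
]


@dataclass
class KineticTrace:
    times: np.ndarray  # s
    fluorescence: np.ndarray  # arbitrary units
    substrate_conc: float = 2.0  # uM
    inhibitor_conc: float = 0.0  # uM
    enzyme: str = "hGIIA"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if (self.times <= 60.0).sum() < 5:
            raise ValueError("need >= 5 points in the first minute")


@dataclass
class DoseResponse:
    concentrations: np.ndarray  # uM, sorted ascending, > 0
    percent_activity: np.ndarray  # % of uninhibited control
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.percent_activity = np.asarray(self.percent_activity, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if not np.all(np.isfinite(self.percent_activity)):
            raise ValueError("activities must be finite")


@dataclass
class InhibitionRecord:
    compound: str
    enzyme: str
    ic50: float | None  # uM; None when censored
    censored_bound: float | None = None  # ">bound" when ic50 is None
    log_p: float | None = None

    def __post_init__(self):
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError("ic50 must be positive or censored")
        if self.ic50 is None and self.censored_bound is None:
            raise ValueError("censored record needs a bound")

    @property
    def is_censored(self) -> bool:
        return self.ic50 is None


@dataclass
class CellAssayRecord:
    condition: str  # "untreated", "IL1b", "IL1b+C8"
    medium: str  # "DMEM", "DMEM+0.1%BSA", "DMEM+2%FCS"
    pge2: float | None = None  # pg
    nitrite: float | None = None  # pmol
    protein: float | None = None  # ug
    absorbance_570: float | None = None
    absorbance_690: float | None = None
    il1b_dose: float = 0.0  # ng/mL
    c8_dose: float = 0.0  # uM

    def __post_init__(self):
        if self.protein is not None and self.protein <= 0:
            raise ValueError("protein must be positive for normalized quantities")


@dataclass
class IC50Fit:
    ic50: float | None  # uM, linear scale; None when censored
    hill: float | None
    censored_bound: float | None = None
    rmse: float = float("nan")
    n_points: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_censored(self) -> bool:
        return self.ic50 is None

    def __str__(self) -> str:
        if self.is_censored:
            return f">{self.censored_bound:g} uM"
        return f"{self.ic50:.3g} uM (hill {self.hill:.2f})"


# ---------------------------------------------------------------------------
# enzymatic assay
# ---------------------------------------------------------------------------

def initial_rate(trace: KineticTrace, window: tuple[float, float] = (0.0, 60.0)) -> float:
    """Least-squares slope of fluorescence over the rate window, AU/min."""
    lo, hi = window
    sel = (trace.times >= lo) & (trace.times <= hi)
    if sel.sum() < 5:
        raise ValueError(f"fewer than 5 points in the rate window [{lo}, {hi}] s")
    res = stats.linregress(trace.times[sel], trace.fluorescence[sel])
    return float(res.slope) * 60.0  # per-second slope -> AU/min


def percent_activity(rate_with: float, rate_without: float) -> float:
    """Residual activity as percent of the uninhibited control rate."""
    if rate_without <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * rate_with / rate_without


def four_pl(conc, ic50, hill, top=100.0, bottom=0.0):
    """Four-parameter logistic on concentration (descending activity)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_ic50(dr: DoseResponse, fix_asymptotes: bool = True,
             crossing: float = 50.0) -> IC50Fit:
    """IC50 by 4PL fit on log10-concentration.

    Asymptotes are fixed at 100/0 by default (the assay reports percent of
    control).  If the observed activities never cross 50% within the tested
    range, the result is censored at the maximum tested concentration —
    a numeric IC50 above that concentration is never reported.
    """
    c = dr.concentrations
    y = dr.percent_activity
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations for an IC50 fit")
    if y.min() > crossing:
        return IC50Fit(ic50=None, hill=None, censored_bound=float(c.max()),
                       n_points=len(c), diagnostics={"reason": "no 50% crossing"})

    logc = np.log10(c)
    # initial guess: interpolate the 50% crossing on the log axis
    order = np.argsort(logc)
    lc, ly = logc[order], y[order]
    idx = np.nonzero(ly <= crossing)[0]
    if idx.size and idx[0] > 0:
        i = idx[0]
        frac = (ly[i - 1] - crossing) / (ly[i - 1] - ly[i])
        log_ic50_0 = lc[i - 1] + frac * (lc[i] - lc[i - 1])
    else:
        log_ic50_0 = float(np.median(lc))

    if fix_asymptotes:
        def model(logc, log_ic50, hill):
            return 100.0 / (1.0 + 10.0 ** (hill * (logc - log_ic50)))
        p0 = [log_ic50_0, 1.0]
    else:
        def model(logc, log_ic50, hill, top, bottom):
            return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))
        p0 = [log_ic50_0, 1.0, 100.0, 0.0]

    popt, _ = optimize.curve_fit(model, logc, y, p0=p0, maxfev=20000)
    pred = model(logc, *popt)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ic50 = 10.0 ** popt[0]
    if ic50 > c.max():
        return IC50Fit(ic50=None, hill=float(popt[1]), censored_bound=float(c.max()),
                       rmse=rmse, n_points=len(c),
                       diagnostics={"reason": "fit crossed above max tested"})
    return IC50Fit(ic50=float(ic50), hill=float(popt[1]), rmse=rmse,
                   n_points=len(c), diagnostics={"params": [float(v) for v in popt]})


# ---------------------------------------------------------------------------
# cellular assays
# ---------------------------------------------------------------------------

def percent_inhibition(mean_treated: float, mean_control: float) -> float:
    """%inhibition = 100 - 100 * (treated / control)."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 - 100.0 * (mean_treated / mean_control)


def fold_induction(mean_treated: float, mean_control: float) -> float:
    """Ratio of stimulated to control means."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return mean_treated / mean_control


def mtt_viability(records: list[CellAssayRecord],
                  reference: list[CellAssayRecord]) -> float:
    """Mean MTT signal (A570 - A690) as percent of the reference condition."""
    def signal(recs):
        vals = [r.absorbance_570 - r.absorbance_690 for r in recs]
        return float(np.mean(vals))

    ref = signal(reference)
    if ref <= 0:
        raise ValueError("reference MTT signal must be positive")
    return 100.0 * signal(records) / ref


def griess_quantify(standards: list[tuple[float, float]],
                    samples: list[float]) -> tuple[np.ndarray, dict]:
    """Nitrite concentrations by inverse prediction from an OLS standard curve.

    standards: (concentration uM, A540) pairs, >= 3, monotone response.
    Negative predictions are clamped to 0 and flagged.
    """
    if len(standards) < 3:
        raise ValueError("need >= 3 standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    a540 = np.array([s[1] for s in standards], dtype=float)
    order = np.argsort(conc)
    if not (np.all(np.diff(a540[order]) > 0) or np.all(np.diff(a540[order]) < 0)):
        raise ValueError("standard response must be monotone in concentration")
    res = stats.linregress(conc, a540)
    if res.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    pred = (np.asarray(samples, dtype=float) - res.intercept) / res.slope
    clamped = pred < 0
    pred = np.where(clamped, 0.0, pred)
    info = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "clamped": clamped.tolist(),
    }
    return pred, info


def normalize_per_protein(amount: float, protein_ug: float) -> float:
    """Amount per ug of whole-cell protein (e.g. pg PGE2 / ug protein)."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    return amount / protein_ug


def densitometry_ratio(cox1: np.ndarray, cox2: np.ndarray,
                       reference_index: int = 0) -> np.ndarray:
    """COX-1/COX-2 band-intensity ratios rescaled so the reference group is 1."""
    cox1 = np.asarray(cox1, dtype=float)
    cox2 = np.asarray(cox2, dtype=float)
    if np.any(cox2 <= 0):
        raise ValueError("COX-2 intensities must be positive")
    ratio = cox1 / cox2
    ref = ratio[reference_index]
    if ref <= 0:
        raise ValueError("reference ratio must be positive")
    return ratio / ref
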