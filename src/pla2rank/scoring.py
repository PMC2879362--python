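"""Binding energy-balance ledger and score/potency rank concordance.

The ledger tracks, per compound, the gas-phase complexation balance

    dE1 = E_int + dE_prot + dE_lig

and the overall balance including continuum solvation

    dE2 = dE1 + dE_solv,   dE_solv = E_solv(complex) - E_solv(lig) - E_solv(prot).

More-negative dE2 predicts tighter binding; lower IC50 means higher measured
potency.  Concordance between the two orderings is quantified with Kendall's
tau-b (tie-corrected), reported together with the concordant/discordant pair
counts so a "same ranking" claim can be checked rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = [
    "EnergyLedgerRow",
    "ConcordanceReport",
    "energy_balance",
    "validate_ledger",
    "rank_concordance",
    "load_energy_table",
    "load_inhibition_table",
    "ledger_from_frame",
]

LEDGER_COLUMNS = [
    "compound", "e_int", "d_e_prot", "d_e_lig", "d_e1",
    "e_solv_complex", "e_solv_lig", "e_solv_prot", "d_e_solv", "d_e2",
]


@dataclass
class EnergyLedgerRow:
    compound: str
    e_int: float
    d_e_prot: float
    d_e_lig: float
    d_e1: float
    e_solv_complex: float
    e_solv_lig: float
    e_solv_prot: float
    d_e_solv: float
    d_e2: float

    def identity_residuals(self) -> dict[str, float]:
        """Deviations of the three ledger identities from zero."""
        return {
            "d_e1": self.d_e1 - (self.e_int + self.d_e_prot + self.d_e_lig),
            "d_e_solv": self.d_e_solv
            - (self.e_solv_complex - self.e_solv_lig - self.e_solv_prot),
            "d_e2": self.d_e2 - (self.d_e1 + self.d_e_solv),
        }


@dataclass
class ConcordanceReport:
    kendall_tau_b: float
    concordant_pairs: int
    discordant_pairs: int
    tied_pairs: int
    is_strictly_concordant: bool
    discordant: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kendall_tau_b": self.kendall_tau_b,
            "concordant_pairs": self.concordant_pairs,
            "discordant_pairs": self.discordant_pairs,
            "tied_pairs": self.tied_pairs,
            "is_strictly_concordant": self.is_strictly_concordant,
            "discordant": self.discordant,
        }


def energy_balance(e_int: float, d_e_prot: float, d_e_lig: float,
                   d_e_solv: float) -> tuple[float, float]:
    """Exact ledger sums: returns (dE1, dE2)."""
    d_e1 = e_int + d_e_prot + d_e_lig
    return d_e1, d_e1 + d_e_solv


def validate_ledger(rows: list[EnergyLedgerRow], tol: float = 0.05) -> list[str]:
    """Check the three ledger identities per row (within tol, which defaults
    to one-decimal printed rounding) and that e_solv_prot is constant across
    rows that share a protein.  Returns a list of human-readable violations;
    empty means the ledger is internally consistent."""
    if not rows:
        raise ValueError("validate_ledger needs at least one row")
    violations: list[str] = []
    for row in rows:
        for key, resid in row.identity_residuals().items():
            if abs(resid) > tol:
                violations.append(
                    f"{row.compound}: {key} off by {resid:+.3f} kcal/mol (tol {tol})"
                )
    prot_values = {row.e_solv_prot for row in rows}
    if len(prot_values) > 1:
        violations.append(
            "e_solv_prot varies across rows sharing a protein: "
            + ", ".join(f"{v:.1f}" for v in sorted(prot_values))
        )
    return violations


def rank_concordance(scores: dict[str, float], potencies: dict[str, float]) -> ConcordanceReport:
    """Kendall tau-b concordance between binding scores and measured IC50s.

    Convention (fixed): more-negative dE2 is the better score and lower IC50
    the better potency, so a concordant model yields positive tau on the raw
    values.  A pair is concordant when both orderings agree, discordant when
    they disagree, tied when either variable ties.
    """
    if set(scores) != set(potencies):
        raise ValueError("scores and potencies must cover the same compounds")
    names = sorted(scores)
    if len(names) < 2:
        raise ValueError("need at least two compounds")
    x = [float(scores[n]) for n in names]
    y = [float(potencies[n]) for n in names]
    conc = disc = tied = 0
    discordant_pairs: list[tuple[str, str]] = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sx = (x[a] > x[b]) - (x[a] < x[b])
            sy = (y[a] > y[b]) - (y[a] < y[b])
            if sx == 0 or sy == 0:
                tied += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
                discordant_pairs.append((names[a], names[b]))
    tau = float(stats.kendalltau(x, y, variant="b").statistic)
    return ConcordanceReport(
        kendall_tau_b=tau,
        concordant_pairs=conc,
        discordant_pairs=disc,
        tied_pairs=tied,
        is_strictly_concordant=disc == 0,
        discordant=discordant_pairs,
    )


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def load_energy_table() -> pd.DataFrame:
    """Packaged per-compound energy-balance table (kcal/mol)."""
    with resources.files("pla2rank.data").joinpath("table1_energy_balances.csv").open() as fh:
        return pd.read_csv(fh)


def load_inhibition_table(censored_as_nan: bool = False) -> pd.DataFrame:
    """Packaged inhibition/log P table.

    The pGIB IC50 column is censored (">100" = no inhibition observed up to
    the highest tested concentration); it is kept as string bounds unless
    censored_as_nan is set.
    """
    with resources.files("pla2rank.data").joinpath("table2_inhibition_logp.csv").open() as fh:
        df = pd.read_csv(fh)
    if censored_as_nan:
        df["ic50_pgib_um"] = pd.to_numeric(df["ic50_pgib_um"], errors="coerce")
    return df


def ledger_from_frame(df: pd.DataFrame) -> list[EnergyLedgerRow]:
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger frame lacks columns: {missing}")
    return [EnergyLedgerRow(**{c: row[c] for c in LEDGER_COLUMNS}) for _, row in df.iterrows()]


def censored_ic50(value) -> tuple[float | None, bool]:
    """Parse an IC50 cell: returns (bound-or-value, is_censored)."""
    if isinstance(value, str) and value.strip().startswith(">"):
        return float(value.strip()[1:]), True
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"IC50 must be positive/finite, got {value!r}")
    return v, False
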