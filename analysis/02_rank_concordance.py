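#!/usr/bin/env python
"""Concordance between computed binding balances and measured potencies.

Computes Kendall tau-b between the overall energy balance dE2 (more negative
= predicted tighter binder) and the hGIIA IC50 (lower = more potent) over
the eight compounds, with explicit pair accounting.

Finding: tau-b = 0.837 with 25 concordant, 2 discordant and 1 tied pair of
28.  The ordering is not strictly identical: C4's more favourable dE2 is
inverted against the C1/C3 measured potencies, and C1/C3 tie at 5.0 uM.
The top (C8) and bottom (C7) of both rankings agree.
"""

import json
from pathlib import Path

from pla2rank.scoring import load_energy_table, load_inhibition_table, rank_concordance

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    t1 = load_energy_table()
    t2 = load_inhibition_table()
    scores = dict(zip(t1.compound, t1.d_e2))
    potencies = dict(zip(t2.compound, t2.ic50_hgiia_um.astype(float)))
    rep = rank_concordance(scores, potencies)

    OUT.mkdir(exist_ok=True)
    (OUT / "concordance.json").write_text(json.dumps(rep.to_dict(), indent=2) + "\n")
    print(f"Kendall tau-b (dE2 vs hGIIA IC50, n=8): {rep.kendall_tau_b:.3f}")
    print(f"pairs: {rep.concordant_pairs} concordant, {rep.discordant_pairs} "
          f"discordant {rep.discordant}, {rep.tied_pairs} tied")
    print(f"strictly concordant: {rep.is_strictly_concordant}")


if __name__ == "__main__":
    main()
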