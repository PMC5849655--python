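#!/usr/bin/env python
"""Fluconazole / siponimod drug-drug interaction predictions.

Four crossover-style trial designs are evaluated.  For each, the
fluconazole steady-state exposure is computed from its own dosing
regimen, a static mechanistic AUC ratio is derived from that average
unbound concentration and the CYP2C9/CYP3A4 inhibition constants, and a
dynamic prediction re-simulates the siponimod dose under the full
time-varying fluconazole profile.  Two static variants are reported: CYP2C9-only
inhibition (the pathway the clinical ~2-fold estimate is attributed to)
and the full panel including CYP3A4, which adds roughly 0.8 to the
ratio at these fluconazole exposures.
"""

from pathlib import Path

import pandas as pd

from sippk import fluconazole, siponimod
from sippk.ddi import InhibitionSpec, dynamic_ddi, perpetrator_exposure, static_aucr
from sippk.io import builtin_regimen

OUT = Path(__file__).resolve().parents[1] / "results"

TRIALS = ["i", "ii", "iii", "iv"]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sip = siponimod()
    flu = fluconazole()

    rows = []
    for trial in TRIALS:
        perp_reg = builtin_regimen(f"fluconazole_trial_{trial}")
        victim_reg = builtin_regimen(f"siponimod_trial_{trial}")
        exposure = perpetrator_exposure(flu, perp_reg)
        aucr_static_2c9 = static_aucr(
            {"CYP2C9": sip.fm["CYP2C9"]}, exposure.css_avg_um,
            {"CYP2C9": flu.ki["CYP2C9"]},
        )
        aucr_static = static_aucr(sip.fm, exposure.css_avg_um, flu.ki)
        dyn = dynamic_ddi(sip, flu, victim_reg, perp_reg,
                          InhibitionSpec.from_perpetrator(flu))
        rows.append({
            "trial": trial,
            "flu_css_avg_um": exposure.css_avg_um,
            "aucr_static_cyp2c9": aucr_static_2c9,
            "aucr_static_full": aucr_static,
            "aucr_dynamic": dyn.aucr,
            "cmax_ratio_dynamic": dyn.cmax_ratio,
            "t_half_base_h": dyn.t_half_base_h,
            "t_half_inhibited_h": dyn.t_half_inhibited_h,
            "auc_kind": dyn.auc_kind,
        })

    table = pd.DataFrame(rows).set_index("trial")
    table.to_csv(OUT / "ddi_predictions.csv")
    print("Fluconazole/siponimod interaction predictions:")
    print(table.round(3).to_string())
    print(
        f"\nTrial i CYP2C9-only static AUCR {table.loc['i', 'aucr_static_cyp2c9']:.2f} "
        "(clinical estimate ~2); adding CYP3A4 inhibition gives "
        f"{table.loc['i', 'aucr_static_full']:.2f}. Dynamic predictions sit "
        "between the two because the inhibitor stays near steady state over "
        "most of the victim's multi-day washout while its average exposure "
        "decays toward the end."
    )


if __name__ == "__main__":
    main()
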