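#!/usr/bin/env python
"""Single-dose siponimod exposure across CYP2C9 genotypes.

Two clearance sources are scanned with a 0.25 mg oral dose: the published
per-genotype CL/F values (treated as inputs) and activity-only scaling of
the wild-type clearance.  The published-clearance scan reproduces the
headline fold-changes (1.4 / 2.7 / 3.0 / 4.5 versus wild type); the
activity-only scan shows the same monotone ordering with larger poor-
metaboliser fold-changes, since it omits any compensatory abundance
assumptions.  The enzyme-contribution redistribution per genotype is
tabulated alongside.
"""

from pathlib import Path

import pandas as pd

from sippk import genotype_scan, recompute_fm, siponimod
from sippk.genotypes import build_activity_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    for source in ("printed", "activity"):
        scan = genotype_scan(dose_mg=0.25, source=source)
        scan.to_csv(OUT / f"genotype_exposure_{source}.csv")
        print(f"--- {source} clearances ---")
        print(
            scan[["cl_f_l_per_h", "auc_inf", "auc_ratio_to_wt", "t_half"]]
            .round(2)
            .to_string()
        )
        print()

    sip = siponimod()
    table = build_activity_table().set_index("genotype")
    rows = {}
    for genotype, row in table.iterrows():
        fm = recompute_fm(sip.fm, row.pg_ratio, row.abundance_multiplier)
        rows[genotype] = {e: 100.0 * f for e, f in fm.as_dict().items()}
    fm_table = pd.DataFrame.from_dict(rows, orient="index")
    fm_table.index.name = "genotype"
    fm_table.to_csv(OUT / "genotype_fm_percent.csv")
    print("Enzyme contribution (% fm) under activity-only redistribution:")
    print(fm_table.round(2).to_string())
    print(
        "\nNote: the *3/*3 CYP2C9 contribution under activity-only scaling "
        f"({fm_table.loc['*3/*3', 'CYP2C9']:.1f}%) exceeds population-simulator "
        "estimates (~11%), which embed additional genotype-specific abundance "
        "assumptions; the abundance-multiplier hook exposes that degree of freedom."
    )


if __name__ == "__main__":
    main()
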