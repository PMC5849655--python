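#!/usr/bin/env python
"""Build the CYP2C9 genotype activity table and allocate intrinsic clearance.

From the two measured variant homozygote activity ratios (0.345 for *2/*2,
0.089 for *3/*3) the full six-genotype table is reconstructed: heterozygotes
by linear interpolation, per-pmol CL_int by proportional scaling from the
wild-type anchor of 49.07 uL/min/pmol.  The retrograde step then allocates
the wild-type oral clearance (4.01 L/h) across enzymes via the documented
liver physiology.
"""

from pathlib import Path

from sippk import build_activity_table, retrograde_clint, siponimod
from sippk.genotypes import genotype_table_to_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    table = build_activity_table()
    genotype_table_to_csv(table, OUT / "genotype_activity_table.csv")
    print("Genotype activity table (PG ratio, CL_int uL/min/pmol):")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print()

    sip = siponimod()
    allocation = retrograde_clint(sip)
    allocation.to_csv(OUT / "retrograde_clint.csv", index=False)
    total = allocation.attrs["clint_total_l_per_h"]
    per_pmol_2c9 = allocation.set_index("enzyme").loc["CYP2C9", "clint_per_pmol_ul_min"]
    print(
        f"Retrograde allocation of CL/F {sip.cl} L/h: total unbound CL_int "
        f"{total:,.0f} L/h; CYP2C9 share {per_pmol_2c9:.1f} uL/min/pmol "
        f"(within 20% of the 49.07 anchor under default physiology)."
    )
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    main()
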