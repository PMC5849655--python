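"""CYP2C9 genotype activity scaling.

The in-vitro pharmacogenetic (PG) activity ratio of a genotype is its
metabolic rate relative to the wild type *1/*1.  Homozygote ratios are
measured; heterozygote ratios are linearly interpolated as the arithmetic
mean of the two parent homozygotes.  Per-pmol intrinsic clearance scales
proportionally: CL_int(g) = PG(g) · CL_int(*1/*1).

The enzyme-contribution vector (fm) of a variant genotype follows from
holding every other enzyme's absolute clearance fixed while CYP2C9's scales
with activity (and, optionally, a genotype-specific abundance multiplier),
then renormalising.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

__all__ = [
    "GENOTYPES",
    "WT",
    "MEASURED_PG_RATIOS",
    "CLINT_WT_PER_PMOL",
    "FM_WT",
    "FmVector",
    "canonical_genotype",
    "interpolate_heterozygote",
    "scale_clint",
    "build_activity_table",
    "recompute_fm",
    "scale_clearance",
    "round_half_away",
    "genotype_table_to_csv",
    "genotype_table_from_csv",
]

WT = "*1/*1"
GENOTYPES = ("*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3")

# Measured homozygote PG ratios from duplicate genotyped-donor incubations,
# and the wild-type per-pmol intrinsic clearance they anchor.
MEASURED_PG_RATIOS: Dict[str, float] = {"*1/*1": 1.0, "*2/*2": 0.345, "*3/*3": 0.089}
CLINT_WT_PER_PMOL = 49.07  # µL/min/pmol CYP2C9

# Wild-type enzyme contribution to siponimod metabolic clearance (fractions).
FM_WT: Dict[str, float] = {
    "CYP2B6": 0.0024,
    "CYP2C8": 0.0154,
    "CYP2C9": 0.8084,
    "CYP2C19": 0.0015,
    "CYP3A4": 0.1723,
}


class GenotypeError(ValueError):
    pass


_GT_RE = re.compile(r"^\*(\d+)\s*/\s*\*(\d+)$")


def canonical_genotype(label: str) -> str:
    """Normalise a genotype label to ``*x/*y`` with x ≤ y."""
    m = _GT_RE.match(label.strip())
    if not m:
        raise GenotypeError(f"unrecognised genotype label {label!r}")
    a, b = sorted(int(g) for g in m.groups())
    return f"*{a}/*{b}"


def _alleles(genotype: str) -> Tuple[int, int]:
    m = _GT_RE.match(canonical_genotype(genotype))
    assert m is not None
    return int(m.group(1)), int(m.group(2))


def interpolate_heterozygote(ratio_a: float, ratio_b: float) -> float:
    """Heterozygote activity as the mean of the two parent homozygote ratios."""
    for r in (ratio_a, ratio_b):
        if not (0.0 <= r <= 1.0):
            raise GenotypeError(f"PG ratio {r!r} outside [0, 1]")
    return 0.5 * (ratio_a + ratio_b)


def scale_clint(pg_ratio: float, clint_wt: float) -> float:
    """Per-pmol intrinsic clearance of a genotype: PG ratio × wild-type CL_int."""
    if pg_ratio < 0:
        raise GenotypeError(f"PG ratio must be non-negative, got {pg_ratio!r}")
    if clint_wt <= 0:
        raise GenotypeError(f"wild-type CL_int must be positive, got {clint_wt!r}")
    return pg_ratio * clint_wt


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (report-time table convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def build_activity_table(
    homozygote_ratios: Optional[Mapping[str, float]] = None,
    clint_wt: float = CLINT_WT_PER_PMOL,
    abundance_multipliers: Optional[Mapping[str, float]] = None,
    genotypes: Iterable[str] = GENOTYPES,
) -> pd.DataFrame:
    """Build the full genotype activity table from measured homozygotes.

    Columns: genotype, pg_ratio, clint_per_pmol, abundance_multiplier,
    is_measured.  Heterozygotes are interpolated; homozygotes must all be
    supplied (wild type ratio must be exactly 1).
    """
    homo = {canonical_genotype(g): r for g, r in (homozygote_ratios or MEASURED_PG_RATIOS).items()}
    if homo.get(WT) != 1.0:
        raise GenotypeError("wild-type homozygote PG ratio must be exactly 1.0")
    mult = {canonical_genotype(g): m for g, m in (abundance_multipliers or {}).items()}
    rows = []
    for gt in genotypes:
        gt = canonical_genotype(gt)
        a, b = _alleles(gt)
        if a == b:
            if gt not in homo:
                raise GenotypeError(f"no measured ratio for homozygote {gt}")
            ratio, measured = homo[gt], True
        else:
            pa, pb = f"*{a}/*{a}", f"*{b}/*{b}"
            if pa not in homo or pb not in homo:
                raise GenotypeError(f"missing parent homozygote for {gt}")
            ratio, measured = interpolate_heterozygote(homo[pa], homo[pb]), False
        rows.append(
            {
                "genotype": gt,
                "pg_ratio": ratio,
                "clint_per_pmol": scale_clint(ratio, clint_wt),
                "abundance_multiplier": float(mult.get(gt, 1.0)),
                "is_measured": measured,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fraction metabolised
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FmVector:
    """Per-enzyme fractions of metabolic clearance; remainder is non-CYP."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = 0.0
        for enzyme, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise GenotypeError(f"fm[{enzyme}]={f!r} outside [0, 1]")
            total += f
        if total > 1.0 + 1e-9:
            raise GenotypeError(f"fm sums to {total:.6f} > 1")

    def __getitem__(self, enzyme: str) -> float:
        return self.fractions[enzyme]

    def get(self, enzyme: str, default: float = 0.0) -> float:
        return self.fractions.get(enzyme, default)

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))

    @property
    def remainder(self) -> float:
        return max(0.0, 1.0 - self.total)

    def as_dict(self) -> Dict[str, float]:
        return dict(self.fractions)


def recompute_fm(
    fm_wt: FmVector | Mapping[str, float],
    pg_ratio: float,
    abundance_multiplier: float = 1.0,
    enzyme: str = "CYP2C9",
) -> FmVector:
    """Redistribute enzyme contributions for a variant genotype.

    The target enzyme's absolute weight scales by ``pg_ratio ×
    abundance_multiplier`` while every other route (CYPs and the non-CYP
    remainder) keeps its wild-type absolute clearance; the weights are then
    renormalised so fm over all routes sums to 1.
    """
    if pg_ratio < 0 or abundance_multiplier < 0:
        raise GenotypeError("pg_ratio and abundance_multiplier must be non-negative")
    fm = fm_wt if isinstance(fm_wt, FmVector) else FmVector(dict(fm_wt))
    weights = fm.as_dict()
    if enzyme not in weights:
        raise GenotypeError(f"{enzyme} not present in fm vector")
    weights[enzyme] = weights[enzyme] * pg_ratio * abundance_multiplier
    total = sum(weights.values()) + fm.remainder
    if total <= 0.0:
        raise GenotypeError("degenerate fm vector: all routes have zero weight")
    return FmVector({enz: w / total for enz, w in weights.items()})


def scale_clearance(
    cl_wt: float,
    fm_2c9_wt: float,
    pg_ratio: float,
    mode: str = "linear",
    *,
    fu: Optional[float] = None,
    fa: float = 1.0,
    fg: float = 1.0,
    physiology=None,
) -> float:
    """Systemic clearance of a variant genotype from the wild-type clearance.

    ``linear`` applies the low-extraction relation
    ``CL(g) = CL_wt · (fm·PG + 1 − fm)``.  ``well-stirred`` round-trips the
    wild-type clearance through the retrograde model: back-calculate total
    unbound CL_int, scale the CYP2C9 share, and run the well-stirred liver
    model forward again (requires ``fu``).
    """
    if cl_wt <= 0:
        raise GenotypeError(f"cl_wt must be positive, got {cl_wt!r}")
    for name, frac in (("fm_2c9_wt", fm_2c9_wt), ("pg_ratio", pg_ratio)):
        if not (0.0 <= frac <= 1.0):
            raise GenotypeError(f"{name}={frac!r} outside [0, 1]")
    if mode == "linear":
        return cl_wt * (fm_2c9_wt * pg_ratio + 1.0 - fm_2c9_wt)
    if mode == "well-stirred":
        if fu is None:
            raise GenotypeError("well-stirred mode requires fu")
        from .retrograde import DEFAULT_PHYSIOLOGY, invert_well_stirred, well_stirred_forward

        phys = physiology or DEFAULT_PHYSIOLOGY
        fu_b = fu  # blood:plasma handled by caller via fu argument
        cl_h = cl_wt * fa * fg
        clint_u = invert_well_stirred(phys.q_h, fu_b, cl_h)
        clint_scaled = clint_u * (fm_2c9_wt * pg_ratio + 1.0 - fm_2c9_wt)
        return well_stirred_forward(phys.q_h, fu_b, clint_scaled) / (fa * fg)
    raise GenotypeError(f"unknown clearance-scaling mode {mode!r}")


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["genotype", "pg_ratio", "clint_per_pmol", "abundance_multiplier"]


def genotype_table_to_csv(table: pd.DataFrame, path) -> None:
    table.loc[:, _TABLE_COLUMNS].to_csv(path, index=False)


def genotype_table_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise GenotypeError(f"genotype table missing columns: {sorted(missing)}")
    df["genotype"] = df["genotype"].map(canonical_genotype)
    return df
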