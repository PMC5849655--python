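"""Retrograde allocation of oral clearance into per-enzyme intrinsic clearance.

The well-stirred liver model relates hepatic clearance to unbound intrinsic
clearance:

    CL_H = Q_H · fu_B · CL_int,u / (Q_H + fu_B · CL_int,u).

Running it "retrograde" inverts this relation: the observed apparent oral
clearance (times fa·fg) fixes CL_H, which is solved for total unbound
CL_int,u; the fraction-metabolised vector then splits the total across
enzymes, and liver scalars (microsomal protein per gram of liver, liver
weight, enzyme abundance) convert each enzyme's share to a per-pmol value.

Physiology defaults here are conventional adult-liver values and are the
package's own documented choices (config-overridable), since per-enzyme
clearance allocation is only defined relative to a stated physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .drugs import DrugModel
from .genotypes import FmVector

__all__ = [
    "PhysiologyDefaults",
    "DEFAULT_PHYSIOLOGY",
    "NonInvertibleClearanceError",
    "well_stirred_forward",
    "invert_well_stirred",
    "retrograde_clint",
]

# Conventional adult enzyme abundances, pmol P450 / mg microsomal protein.
_DEFAULT_ABUNDANCE = {
    "CYP1A2": 52.0,
    "CYP2B6": 17.0,
    "CYP2C8": 24.0,
    "CYP2C9": 73.0,
    "CYP2C19": 14.0,
    "CYP2D6": 8.0,
    "CYP3A4": 137.0,
}


class NonInvertibleClearanceError(ValueError):
    """Hepatic clearance at or above liver blood flow: retrograde step undefined."""


@dataclass(frozen=True)
class PhysiologyDefaults:
    """Liver physiology used for retrograde scaling (all strictly positive)."""

    q_h: float = 97.0  # hepatic blood flow, L/h
    liver_weight_g: float = 1650.0
    mppgl: float = 40.0  # mg microsomal protein / g liver
    body_weight: float = 70.0  # kg
    blood_to_plasma: float = 1.0
    abundance: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ABUNDANCE))

    def __post_init__(self) -> None:
        for attr in ("q_h", "liver_weight_g", "mppgl", "body_weight", "blood_to_plasma"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        for enzyme, ab in self.abundance.items():
            if ab <= 0:
                raise ValueError(f"abundance[{enzyme}] must be strictly positive")

    def enzyme_pmol(self, enzyme: str) -> Optional[float]:
        """Whole-liver enzyme amount in pmol, or None if abundance unknown."""
        ab = self.abundance.get(enzyme)
        if ab is None:
            return None
        return ab * self.mppgl * self.liver_weight_g


DEFAULT_PHYSIOLOGY = PhysiologyDefaults()


def well_stirred_forward(q_h: float, fu_b: float, clint_u: float) -> float:
    """Hepatic clearance from unbound intrinsic clearance (L/h).

    Bounded above by Q_H and monotone increasing in CL_int,u.
    """
    if q_h <= 0 or fu_b <= 0 or clint_u < 0:
        raise ValueError("q_h and fu_b must be positive; clint_u non-negative")
    x = fu_b * clint_u
    return q_h * x / (q_h + x)


def invert_well_stirred(q_h: float, fu_b: float, cl_h: float) -> float:
    """Unbound intrinsic clearance producing hepatic clearance ``cl_h`` (L/h)."""
    if q_h <= 0 or fu_b <= 0 or cl_h < 0:
        raise ValueError("q_h and fu_b must be positive; cl_h non-negative")
    if cl_h >= q_h:
        raise NonInvertibleClearanceError(
            f"hepatic clearance {cl_h:.3g} L/h reaches hepatic blood flow "
            f"Q_H = {q_h:.3g} L/h; the well-stirred model cannot be inverted "
            "at or beyond the flow limit"
        )
    return cl_h * q_h / (fu_b * (q_h - cl_h))


def retrograde_clint(
    model: DrugModel,
    fm: Optional[FmVector | Mapping[str, float]] = None,
    physiology: PhysiologyDefaults = DEFAULT_PHYSIOLOGY,
) -> pd.DataFrame:
    """Allocate a drug's oral clearance to per-enzyme intrinsic clearances.

    Returns one row per route with columns ``enzyme``, ``fm``,
    ``clint_u_l_per_h`` (absolute unbound CL_int share) and
    ``clint_per_pmol_ul_min`` (µL/min/pmol, NaN for routes without a known
    abundance, including the non-enzymatic remainder).

    The hepatic clearance entering the inversion is CL/F × fa·fg; the
    forward well-stirred round trip therefore recovers CL/F exactly.
    """
    if fm is None:
        fm = model.fm
    fm_vec = fm if isinstance(fm, FmVector) else FmVector(dict(fm))
    cl_h = model.cl * model.fa * model.fg
    clint_total = invert_well_stirred(physiology.q_h, model.fu / physiology.blood_to_plasma, cl_h)

    rows = []
    shares = dict(fm_vec.as_dict())
    if fm_vec.remainder > 1e-12:
        shares["other"] = fm_vec.remainder
    for enzyme, frac in shares.items():
        clint_abs = frac * clint_total  # L/h
        pmol = physiology.enzyme_pmol(enzyme)
        per_pmol = float("nan")
        if pmol is not None:
            per_pmol = clint_abs * 1e6 / 60.0 / pmol  # L/h -> µL/min, then per pmol
        rows.append(
            {
                "enzyme": enzyme,
                "fm": frac,
                "clint_u_l_per_h": clint_abs,
                "clint_per_pmol_ul_min": per_pmol,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["clint_total_l_per_h"] = clint_total
    df.attrs["cl_h_l_per_h"] = cl_h
    return df
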