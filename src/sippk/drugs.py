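"""Drug-model containers and the shipped siponimod / fluconazole parameter sets.

A :class:`DrugModel` bundles the dose-independent disposition parameters of one
compound: first-order absorption rate ``ka``, apparent volume of distribution
``v`` (per kg body weight), apparent oral clearance ``cl`` (CL/F), the binding
and availability fractions ``fu``/``fa``/``fg``, the fraction-metabolised
vector ``fm`` (victim role) and the competitive inhibition constants ``ki``
(perpetrator role).

Units are fixed package-wide: time in hours, amounts in mg, volumes in litres,
clearances in L/h, concentrations in ng/mL, inhibition constants in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional


class DrugModelError(ValueError):
    """Invalid drug-model parameterisation."""


def _check_fraction(name: str, value: float, *, allow_zero: bool = False) -> None:
    lo_ok = value >= 0.0 if allow_zero else value > 0.0
    if not (lo_ok and value <= 1.0):
        raise DrugModelError(f"{name} must be a fraction in (0, 1], got {value!r}")


@dataclass(frozen=True)
class DrugModel:
    """Dose-independent pharmacokinetic parameter set for one compound.

    Parameters
    ----------
    name:
        Compound label used in output provenance.
    mw:
        Molecular weight in g/mol (used for ng/mL -> µM conversions).
    ka:
        First-order absorption rate constant, 1/h.
    v:
        Apparent volume of distribution, L/kg.
    cl:
        Apparent oral clearance CL/F, L/h.
    fu:
        Unbound fraction in plasma.
    fa, fg:
        Fraction absorbed and fraction escaping gut metabolism.
    body_weight:
        kg; volumes are scaled by it.
    fm:
        Fraction of metabolic clearance per enzyme (victim role). The
        remainder ``1 - sum(fm)`` is treated as non-CYP clearance.
    ki:
        Competitive inhibition constant per enzyme in µM (perpetrator role).
    blood_to_plasma:
        Blood-to-plasma concentration ratio; the unbound fraction in blood is
        ``fu / blood_to_plasma``.
    """

    name: str
    mw: float
    ka: float
    v: float
    cl: float
    fu: float = 1.0
    fa: float = 1.0
    fg: float = 1.0
    body_weight: float = 70.0
    fm: Mapping[str, float] = field(default_factory=dict)
    ki: Mapping[str, float] = field(default_factory=dict)
    blood_to_plasma: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("mw", "ka", "v", "cl", "body_weight", "blood_to_plasma"):
            if getattr(self, attr) <= 0.0:
                raise DrugModelError(f"{attr} must be > 0, got {getattr(self, attr)!r}")
        _check_fraction("fu", self.fu)
        _check_fraction("fa", self.fa)
        _check_fraction("fg", self.fg)
        fm_sum = 0.0
        for enzyme, frac in self.fm.items():
            _check_fraction(f"fm[{enzyme}]", frac, allow_zero=True)
            fm_sum += frac
        if fm_sum > 1.0 + 1e-9:
            raise DrugModelError(f"fm fractions sum to {fm_sum:.6f} > 1")
        for enzyme, ki in self.ki.items():
            if ki <= 0.0:
                raise DrugModelError(f"ki[{enzyme}] must be > 0, got {ki!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def v_total(self) -> float:
        """Total apparent volume of distribution, L."""
        return self.v * self.body_weight

    @property
    def k_el(self) -> float:
        """First-order elimination rate constant CL / V, 1/h."""
        return self.cl / self.v_total

    @property
    def t_half(self) -> float:
        """Elimination half-life ln(2)/k, h."""
        import math

        return math.log(2.0) / self.k_el

    @property
    def fu_blood(self) -> float:
        """Unbound fraction referenced to whole blood, fu / (B:P)."""
        return self.fu / self.blood_to_plasma

    def with_clearance(self, cl: float) -> "DrugModel":
        """Copy of this model with a different oral clearance."""
        return replace(self, cl=cl)

    def ngml_to_um(self, conc_ngml: float) -> float:
        """Convert a plasma concentration from ng/mL to µM via the MW."""
        return conc_ngml / self.mw


def siponimod(cl: Optional[float] = None) -> DrugModel:
    """The shipped siponimod model (victim).

    Loaded from the packaged parameter file; ``cl`` overrides the wild-type
    apparent oral clearance (used for genotype scans).
    """
    from .io import load_builtin_drug

    model = load_builtin_drug("siponimod")
    return model if cl is None else model.with_clearance(cl)


def fluconazole() -> DrugModel:
    """The shipped fluconazole model (perpetrator)."""
    from .io import load_builtin_drug

    return load_builtin_drug("fluconazole")
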