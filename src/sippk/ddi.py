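"""Mechanistic drug–drug interaction prediction under competitive inhibition.

Static model: with a representative inhibitor concentration I the victim's
AUC fold-change is

    AUCR = 1 / ( Σ_i fm_i / (1 + I/Ki_i)  +  (1 − Σ_i fm_i) ),

where the sum runs over inhibited enzymes and the complement collects
uninhibited routes.  Dynamic model: the victim's elimination rate is scaled
at every instant by the same factor evaluated at the simulated inhibitor
concentration I(t); with a constant I(t) the two routes coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np

from .drugs import DrugModel
from .genotypes import FmVector
from .pk import ConcentrationProfile, NCASummary, Regimen, nca, simulate, simulate_ode

__all__ = [
    "InhibitionSpec",
    "SteadyStateExposure",
    "DDIResult",
    "NotAtSteadyStateError",
    "inhibition_factor",
    "static_aucr",
    "perpetrator_exposure",
    "time_to_steady_state",
    "dynamic_ddi",
    "simulate_victim_inhibited",
]


class NotAtSteadyStateError(RuntimeError):
    """Simulation horizon too short for the perpetrator to reach steady state."""


@dataclass(frozen=True)
class InhibitionSpec:
    """Perpetrator inhibition parameters and the concentration convention.

    ``basis`` selects total vs unbound systemic concentration; ``metric``
    selects which steady-state statistic drives the static model.
    """

    ki: Mapping[str, float]  # µM per enzyme
    mw: float  # g/mol
    fu: float = 1.0
    basis: str = "total"  # {"total", "unbound"}
    metric: str = "average"  # {"average", "max", "trough"}

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        for enzyme, ki in self.ki.items():
            if ki <= 0:
                raise ValueError(f"ki[{enzyme}] must be positive")
        if self.basis not in ("total", "unbound"):
            raise ValueError(f"unknown concentration basis {self.basis!r}")
        if self.metric not in ("average", "max", "trough"):
            raise ValueError(f"unknown concentration metric {self.metric!r}")

    @classmethod
    def from_perpetrator(
        cls, perpetrator: DrugModel, basis: str = "total", metric: str = "average"
    ) -> "InhibitionSpec":
        return cls(
            ki=dict(perpetrator.ki), mw=perpetrator.mw, fu=perpetrator.fu,
            basis=basis, metric=metric,
        )

    def effective_um(self, conc_um):
        """Apply the concentration basis (unbound multiplies by fu)."""
        return conc_um * self.fu if self.basis == "unbound" else conc_um


def inhibition_factor(
    i_um: float, fm: FmVector | Mapping[str, float], ki: Mapping[str, float]
) -> float:
    """Fractional victim clearance remaining at inhibitor concentration I.

    Enzymes carrying no Ki, and the non-enzymatic remainder, contribute their
    fm unchanged.  Equals 1 at I = 0 and decreases monotonically with I.
    """
    if i_um < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    fm_vec = fm if isinstance(fm, FmVector) else FmVector(dict(fm))
    factor = fm_vec.remainder
    for enzyme, frac in fm_vec.as_dict().items():
        ki_e = ki.get(enzyme)
        factor += frac if ki_e is None else frac / (1.0 + i_um / ki_e)
    return factor


def static_aucr(
    fm: FmVector | Mapping[str, float], i_um: float, ki: Mapping[str, float]
) -> float:
    """Closed-form victim AUC fold-change at a fixed inhibitor concentration."""
    return 1.0 / inhibition_factor(i_um, fm, ki)


# ---------------------------------------------------------------------------
# perpetrator exposure
# ---------------------------------------------------------------------------


@dataclass
class SteadyStateExposure:
    css_avg_ngml: float
    css_max_ngml: float
    css_min_ngml: float
    css_avg_um: float
    css_max_um: float
    css_min_um: float
    tau_h: float
    interval_start_h: float


def perpetrator_exposure(
    model: DrugModel, regimen: Regimen, *, dt: float = 0.25, ss_tol: float = 0.02
) -> SteadyStateExposure:
    """Steady-state concentration metrics over the final dosing interval.

    The last full interval's AUC must agree with the previous interval's
    within ``ss_tol`` (2% default), otherwise the regimen has not reached
    steady state within its own horizon and an error is raised.
    """
    tau = regimen.maintenance_interval()
    t_last = regimen.last_time
    grid = np.arange(0.0, t_last + tau + dt / 2, dt)
    profile = simulate(model, regimen, grid=grid)

    def interval_auc(t0: float) -> float:
        sel = (profile.time >= t0 - 1e-9) & (profile.time <= t0 + tau + 1e-9)
        return float(np.trapezoid(profile.conc[sel], profile.time[sel]))

    auc_last = interval_auc(t_last)
    auc_prev = interval_auc(t_last - tau)
    if auc_prev <= 0 or abs(auc_last - auc_prev) / auc_prev > ss_tol:
        raise NotAtSteadyStateError(
            f"last-interval AUC differs from previous by "
            f"{abs(auc_last - auc_prev) / max(auc_prev, 1e-12):.1%} (> {ss_tol:.0%}); "
            "extend the regimen horizon"
        )
    sel = (profile.time >= t_last - 1e-9) & (profile.time <= t_last + tau + 1e-9)
    c = profile.conc[sel]
    css_avg = auc_last / tau
    css_max = float(c.max())
    css_min = float(c.min())
    return SteadyStateExposure(
        css_avg_ngml=css_avg,
        css_max_ngml=css_max,
        css_min_ngml=css_min,
        css_avg_um=model.ngml_to_um(css_avg),
        css_max_um=model.ngml_to_um(css_max),
        css_min_um=model.ngml_to_um(css_min),
        tau_h=tau,
        interval_start_h=t_last,
    )


def time_to_steady_state(
    model: DrugModel,
    regimen: Regimen,
    *,
    fraction: float = 0.9,
    period_h: float = 24.0,
    dt: float = 0.25,
) -> float:
    """First period start (h) whose average concentration reaches
    ``fraction`` of the asymptotic maintenance-period average."""
    maint_dose = regimen.events[-1].amount_mg
    tau = regimen.maintenance_interval()
    doses_per_period = period_h / tau
    css_avg_asymptote = (
        maint_dose * doses_per_period / (model.cl * period_h) * 1000.0
    )  # mg/L -> ng/mL
    horizon = regimen.last_time + period_h
    grid = np.arange(0.0, horizon + dt / 2, dt)
    profile = simulate(model, regimen, grid=grid)
    start = 0.0
    while start + period_h <= grid[-1] + 1e-9:
        sel = (profile.time >= start - 1e-9) & (profile.time <= start + period_h + 1e-9)
        avg = float(np.trapezoid(profile.conc[sel], profile.time[sel])) / period_h
        if avg >= fraction * css_avg_asymptote:
            return start
        start += period_h
    raise NotAtSteadyStateError(
        f"{fraction:.0%} of steady state not reached within the regimen horizon"
    )


# ---------------------------------------------------------------------------
# dynamic simulation
# ---------------------------------------------------------------------------


@dataclass
class DDIResult:
    aucr: float
    cmax_ratio: float
    t_half_base_h: float
    t_half_inhibited_h: float
    nca_base: NCASummary
    nca_inhibited: NCASummary
    profile_base: ConcentrationProfile
    profile_inhibited: ConcentrationProfile
    auc_kind: str  # "auc_inf" or "auc_last"


def simulate_victim_inhibited(
    victim: DrugModel,
    victim_regimen: Regimen,
    inhibitor_conc_um: Callable[[float], float],
    ki: Mapping[str, float],
    grid: np.ndarray,
    *,
    breakpoints=None,
    rtol: float = 1e-9,
) -> ConcentrationProfile:
    """Victim profile with elimination scaled by a time-varying inhibitor.

    ``inhibitor_conc_um`` is evaluated at each integrator step; pass the
    inhibitor's dose times as ``breakpoints`` so the kinks in I(t) fall on
    integration segment boundaries.
    """
    fm = victim.fm

    def scale(t: float) -> float:
        return inhibition_factor(float(inhibitor_conc_um(t)), fm, ki)

    return simulate_ode(
        victim,
        victim_regimen,
        grid,
        elimination_scale=scale,
        breakpoints=breakpoints,
        rtol=rtol,
        atol=1e-12,
        metadata={"scenario": "inhibited"},
    )


def _perp_conc_um(perpetrator: DrugModel, regimen: Regimen, spec: InhibitionSpec):
    """Closed-form perpetrator concentration (µM, chosen basis) as f(t)."""
    times = regimen.times
    amounts = regimen.amounts
    ka, k, v = perpetrator.ka, perpetrator.k_el, perpetrator.v_total

    def conc(t: float) -> float:
        dt = t - times
        mask = dt > 0
        if not mask.any():
            return 0.0
        d = dt[mask]
        scale = amounts[mask] * 1000.0 / v
        terms = scale * ka / (ka - k) * (np.exp(-k * d) - np.exp(-ka * d))
        ngml = float(terms.sum())
        return float(spec.effective_um(perpetrator.ngml_to_um(ngml)))

    return conc


def dynamic_ddi(
    victim: DrugModel,
    perpetrator: DrugModel,
    victim_regimen: Regimen,
    perp_regimen: Regimen,
    spec: Optional[InhibitionSpec] = None,
    *,
    dt: float = 0.5,
    t_end: Optional[float] = None,
    n_half_lives: float = 10.0,
    rtol: float = 1e-9,
) -> DDIResult:
    """Paired victim simulations with and without the perpetrator.

    The baseline run uses the closed-form superposition engine; the
    inhibited run integrates the victim ODE with its elimination scaled by
    the instantaneous perpetrator concentration.  AUCR and the Cmax ratio
    come from NCA of the paired profiles (AUC extrapolated to infinity when
    both terminal fits succeed, AUC_last otherwise).
    """
    if spec is None:
        spec = InhibitionSpec.from_perpetrator(perpetrator)
    if t_end is None:
        # budget the horizon for the slowed elimination under average inhibition
        maint = perp_regimen.events[-1].amount_mg
        tau = perp_regimen.maintenance_interval() if len(perp_regimen.events) > 1 else 24.0
        css_guess = spec.effective_um(
            perpetrator.ngml_to_um(maint / (perpetrator.cl * tau) * 1000.0)
        )
        stretch = static_aucr(victim.fm, css_guess, spec.ki)
        t_end = victim_regimen.last_time + n_half_lives * victim.t_half * stretch
    grid = np.arange(0.0, t_end + dt / 2, dt)

    base = simulate(victim, victim_regimen, grid=grid, metadata={"scenario": "baseline"})
    conc_fn = _perp_conc_um(perpetrator, perp_regimen, spec)
    inhibited = simulate_victim_inhibited(
        victim,
        victim_regimen,
        conc_fn,
        spec.ki,
        grid,
        breakpoints=perp_regimen.times,
        rtol=rtol,
    )

    nca_base = nca(base)
    nca_inh = nca(inhibited)
    if nca_base.terminal_ok and nca_inh.terminal_ok:
        aucr = nca_inh.auc_inf / nca_base.auc_inf
        kind = "auc_inf"
    else:
        aucr = nca_inh.auc_last / nca_base.auc_last
        kind = "auc_last"
    return DDIResult(
        aucr=aucr,
        cmax_ratio=nca_inh.cmax / nca_base.cmax,
        t_half_base_h=nca_base.t_half,
        t_half_inhibited_h=nca_inh.t_half,
        nca_base=nca_base,
        nca_inhibited=nca_inh,
        profile_base=base,
        profile_inhibited=inhibited,
        auc_kind=kind,
    )
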