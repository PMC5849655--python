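"""One-compartment oral PK engine with superposition dosing and NCA.

The plasma concentration after a single oral dose is the classic Bateman term

    C(t) = F·D·ka / (V·(ka − k)) · (exp(−k·t) − exp(−ka·t)),

with the analytic limit F·D·k·t·exp(−k·t)/V when ka → k.  Multi-dose profiles
are the superposition of one term per dose event, which is exact for a linear
system.  An ODE integrator (`simulate_ode`) provides the independent numerical
route; it also accepts a time-varying elimination-scale function, which is how
dynamic drug–drug-interaction simulations slow the victim's elimination, and
an optional peripheral distribution compartment.

Non-compartmental analysis follows the conventional rules: linear-up /
log-down trapezoidal AUC, terminal slope λz from the best-R² log-linear
suffix window of at most the last 10 post-peak points, AUC extrapolated to
infinity as ``AUC_last + C_last/λz``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .drugs import DrugModel

__all__ = [
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "NCASummary",
    "Peripheral",
    "simulate",
    "simulate_ode",
    "nca",
]

MG_PER_L_TO_NG_PER_ML = 1000.0  # 1 mg/L == 1000 ng/mL == 1 µg/L · 1000 ... (ng/mL = µg/L)


class RegimenError(ValueError):
    """Invalid dosing regimen."""


@dataclass(frozen=True)
class DoseEvent:
    amount_mg: float
    time_h: float


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of oral dose events."""

    events: Tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time_h for e in self.events]
        if any(t < 0 for t in times):
            raise RegimenError("dose times must be non-negative")
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise RegimenError("dose events must be time-sorted")
        if any(e.amount_mg <= 0 for e in self.events):
            raise RegimenError("dose amounts must be positive")

    # -- builders -----------------------------------------------------------

    @classmethod
    def single(cls, amount_mg: float, time_h: float = 0.0) -> "Regimen":
        return cls((DoseEvent(amount_mg, time_h),))

    @classmethod
    def repeated(
        cls, amount_mg: float, n: int, interval_h: float, start_h: float = 0.0
    ) -> "Regimen":
        if n < 1:
            raise RegimenError("need at least one dose")
        return cls(tuple(DoseEvent(amount_mg, start_h + i * interval_h) for i in range(n)))

    @classmethod
    def qd(cls, amount_mg: float, n_days: int, start_h: float = 0.0) -> "Regimen":
        """Once daily for ``n_days`` days."""
        return cls.repeated(amount_mg, n_days, 24.0, start_h)

    @classmethod
    def bid(cls, amount_mg: float, n_days: int, start_h: float = 0.0) -> "Regimen":
        """Twice daily (12 h apart) for ``n_days`` days."""
        return cls.repeated(amount_mg, 2 * n_days, 12.0, start_h)

    def __add__(self, other: "Regimen") -> "Regimen":
        return Regimen(tuple(sorted(self.events + other.events, key=lambda e: e.time_h)))

    def shifted(self, dt_h: float) -> "Regimen":
        return Regimen(tuple(DoseEvent(e.amount_mg, e.time_h + dt_h) for e in self.events))

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(tuple(DoseEvent(e.amount_mg * factor, e.time_h) for e in self.events))

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_h for e in self.events])

    @property
    def amounts(self) -> np.ndarray:
        return np.array([e.amount_mg for e in self.events])

    @property
    def last_time(self) -> float:
        return self.events[-1].time_h if self.events else 0.0

    def maintenance_interval(self) -> float:
        """Dosing interval τ of the trailing maintenance phase (h)."""
        if len(self.events) < 2:
            raise RegimenError("regimen has no repeated doses; interval undefined")
        return self.events[-1].time_h - self.events[-2].time_h


@dataclass
class ConcentrationProfile:
    """A simulated plasma concentration–time course."""

    time: np.ndarray  # h, strictly increasing
    conc: np.ndarray  # ng/mL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.time.shape != self.conc.shape:
            raise ValueError("time and concentration grids differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.conc < -1e-9):
            raise ValueError("negative concentrations")
        self.conc = np.clip(self.conc, 0.0, None)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_h": self.time, "conc_ng_per_ml": self.conc})
        for key, val in self.metadata.items():
            if np.isscalar(val) or isinstance(val, str):
                df[key] = val
        return df


@dataclass(frozen=True)
class Peripheral:
    """Optional peripheral distribution compartment (minimal-PBPK flavour).

    ``q`` is the inter-compartmental clearance (L/h) and ``v`` the peripheral
    volume (L/kg).  Off by default throughout the package.
    """

    q: float
    v: float


def _bateman_terms(
    t: np.ndarray, events: Sequence[DoseEvent], ka: float, k: float, v_total: float, f: float
) -> np.ndarray:
    """Superposed single-dose oral terms, ng/mL."""
    conc = np.zeros_like(t, dtype=float)
    for ev in events:
        dt = t - ev.time_h
        mask = dt > 0
        if not np.any(mask):
            continue
        d = dt[mask]
        scale = f * ev.amount_mg * MG_PER_L_TO_NG_PER_ML / v_total
        if abs(ka - k) > 1e-10 * max(ka, k):
            term = scale * ka / (ka - k) * (np.exp(-k * d) - np.exp(-ka * d))
        else:  # flip-flop degeneracy: analytic limit, not an error
            term = scale * k * d * np.exp(-k * d)
        conc[mask] += term
    return conc


def _default_grid(model: DrugModel, regimen: Regimen, dt: float, n_half_lives: float) -> np.ndarray:
    horizon = regimen.last_time + n_half_lives * model.t_half
    n = int(math.ceil(horizon / dt))
    return np.linspace(0.0, n * dt, n + 1)


def simulate(
    model: DrugModel,
    regimen: Regimen,
    *,
    grid: Optional[np.ndarray] = None,
    dt: float = 0.25,
    n_half_lives: float = 10.0,
    dose_scale: float = 1.0,
    metadata: Optional[dict] = None,
) -> ConcentrationProfile:
    """Closed-form superposition simulation of a multi-dose oral regimen.

    With no explicit ``grid``, sampling runs at ``dt`` spacing from zero to
    the last dose plus ``n_half_lives`` elimination half-lives (enough for
    AUC extrapolation targets).  ``dose_scale`` multiplies every dose (the
    bioavailability F where the clearance is not already apparent).
    """
    if grid is None:
        grid = _default_grid(model, regimen, dt, n_half_lives)
    grid = np.asarray(grid, dtype=float)
    if len(regimen.events) == 0:
        conc = np.zeros_like(grid)
    else:
        conc = _bateman_terms(grid, regimen.events, model.ka, model.k_el, model.v_total, dose_scale)
    meta = {"drug": model.name, "engine": "superposition"}
    if metadata:
        meta.update(metadata)
    return ConcentrationProfile(grid, conc, meta)


def simulate_ode(
    model: DrugModel,
    regimen: Regimen,
    grid: np.ndarray,
    *,
    elimination_scale: Optional[Callable[[float], float]] = None,
    peripheral: Optional[Peripheral] = None,
    dose_scale: float = 1.0,
    breakpoints: Optional[Sequence[float]] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    metadata: Optional[dict] = None,
) -> ConcentrationProfile:
    """Numerical-integration route for the same model (oracle + DDI engine).

    State is tracked in amounts (µg): gut depot, central, optional peripheral.
    ``elimination_scale`` multiplies the elimination rate at each instant —
    a constant 1.0 reproduces `simulate`; a time-varying factor implements
    competitive-inhibition DDI.  ``breakpoints`` are extra segment boundaries
    (e.g. perpetrator dose times, where the inhibitor profile has kinks).

    Raises
    ------
    RuntimeError
        If the integrator fails; the message carries the solver report.
    """
    grid = np.asarray(grid, dtype=float)
    v1 = model.v_total
    ka = model.ka
    cl = model.cl
    scale_fn = elimination_scale or (lambda t: 1.0)

    def rhs(t: float, y: np.ndarray) -> list:
        gut, central = y[0], y[1]
        dgut = -ka * gut
        dcentral = ka * gut - cl * scale_fn(t) * central / v1
        if peripheral is not None:
            per = y[2]
            v2 = peripheral.v * model.body_weight
            flux = peripheral.q * (central / v1 - per / v2)
            dcentral -= flux
            return [dgut, dcentral, flux]
        return [dgut, dcentral]

    # segment at dose times and user breakpoints so events stay exact
    cuts = {float(grid[0]), float(grid[-1])}
    cuts.update(float(e.time_h) for e in regimen.events if grid[0] <= e.time_h <= grid[-1])
    if breakpoints is not None:
        cuts.update(float(b) for b in breakpoints if grid[0] < b < grid[-1])
    cuts = sorted(cuts)

    dose_at = {}
    for ev in regimen.events:
        dose_at.setdefault(float(ev.time_h), 0.0)
        dose_at[float(ev.time_h)] += ev.amount_mg * MG_PER_L_TO_NG_PER_ML * dose_scale

    n_states = 3 if peripheral is not None else 2
    y = np.zeros(n_states)
    if cuts[0] in dose_at:
        y[0] += dose_at[cuts[0]]
    conc = np.full_like(grid, np.nan)
    if grid[0] == cuts[0]:
        conc[0] = y[1] / v1

    for t0, t1 in zip(cuts, cuts[1:]):
        sel = (grid > t0) & (grid <= t1)
        t_eval = grid[sel]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{t0}, {t1}] h: {sol.message} "
                f"(nfev={sol.nfev}, last step at t={sol.t[-1] if sol.t.size else t0})"
            )
        if t_eval.size:
            conc[sel] = sol.y[1] / v1
        y = sol.y[:, -1] if sol.t.size else y
        if sol.t.size and sol.t[-1] != t1:  # pragma: no cover - defensive
            raise RuntimeError(f"integrator stopped early at t={sol.t[-1]}")
        if t1 in dose_at:
            y = y.copy()
            y[0] += dose_at[t1]

    # grid points before the first cut (all-zero pre-dose baseline)
    conc[np.isnan(conc)] = 0.0
    meta = {"drug": model.name, "engine": "ode"}
    if metadata:
        meta.update(metadata)
    return ConcentrationProfile(grid, conc, meta)


# ---------------------------------------------------------------------------
# Non-compartmental analysis
# ---------------------------------------------------------------------------


@dataclass
class NCASummary:
    auc_last: float  # ng·h/mL
    auc_inf: float  # ng·h/mL (nan if terminal phase undefined)
    cmax: float  # ng/mL
    tmax: float  # h
    t_half: float  # h (nan if undefined)
    lambda_z: float  # 1/h
    r_squared: float
    n_terminal: int
    extrap_pct: float  # % of AUC_inf beyond the last observation
    terminal_ok: bool


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """Trapezoidal AUC: linear while rising, log-linear while falling."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    seg = np.empty_like(dt)
    log_ok = (c2 < c1) & (c2 > 0) & (c1 > 0)
    lin = ~log_ok
    seg[lin] = 0.5 * (c1[lin] + c2[lin]) * dt[lin]
    seg[log_ok] = (c1[log_ok] - c2[log_ok]) / np.log(c1[log_ok] / c2[log_ok]) * dt[log_ok]
    return float(seg.sum())


def _terminal_fit(
    t: np.ndarray, c: np.ndarray, tmax_idx: int, max_points: int, min_points: int
) -> Tuple[float, float, int]:
    """Best-R² suffix window log-linear fit; returns (λz, R², n_points)."""
    post = np.nonzero((np.arange(len(t)) > tmax_idx) & (c > 0))[0]
    cand = post[-max_points:]
    best = (np.nan, -np.inf, 0)
    for start in range(0, len(cand) - min_points + 1):
        idx = cand[start:]
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if slope < 0 and r2 > best[1]:
            best = (-slope, r2, len(idx))
    return best


def nca(
    profile: ConcentrationProfile,
    *,
    max_terminal_points: int = 10,
    min_terminal_points: int = 3,
    r2_threshold: float = 0.8,
) -> NCASummary:
    """Model-free exposure summary of a concentration–time profile."""
    t, c = profile.time, profile.conc
    if len(t) < 3:
        raise ValueError("need at least 3 points for NCA")
    tmax_idx = int(np.argmax(c))
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])
    auc_last = _auc_lin_up_log_down(t, c)

    lam, r2, n_term = _terminal_fit(t, c, tmax_idx, max_terminal_points, min_terminal_points)
    terminal_ok = bool(np.isfinite(lam) and r2 >= r2_threshold)
    if terminal_ok:
        t_half = math.log(2.0) / lam
        c_last = float(c[c > 0][-1]) if np.any(c > 0) else 0.0
        auc_inf = auc_last + c_last / lam
        extrap = 100.0 * (auc_inf - auc_last) / auc_inf if auc_inf > 0 else 0.0
    else:
        t_half = float("nan")
        auc_inf = float("nan")
        extrap = float("nan")
    return NCASummary(
        auc_last=auc_last,
        auc_inf=auc_inf,
        cmax=cmax,
        tmax=tmax,
        t_half=t_half,
        lambda_z=lam,
        r_squared=r2 if np.isfinite(r2) else float("nan"),
        n_terminal=n_term,
        extrap_pct=extrap,
        terminal_ok=terminal_ok,
    )
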