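# Methods

This document describes the models, parameters and numerical choices
implemented in `sippk`, in the order the pipeline uses them.

## 1. Genotype activity scaling (`sippk.genotypes`)

CYP2C9 diplotypes are written `*x/*y` with `x ≤ y`
(`canonical_genotype` normalises the order). Activity is expressed as a
pharmacogenetic (PG) ratio relative to `*1/*1`. Measured inputs are the
homozygote ratios:

| genotype | PG ratio | status |
|---|---|---|
| \*1/\*1 | 1.000 | reference |
| \*2/\*2 | 0.345 | measured |
| \*3/\*3 | 0.089 | measured |

Heterozygote ratios are the arithmetic mean of the two parent
homozygotes (gene-dose additivity on the activity scale):
\*1/\*2 = 0.6725, \*1/\*3 = 0.5445, \*2/\*3 = 0.2170. Per-pmol intrinsic
clearance scales proportionally from the wild-type anchor of
49.07 µL/min/pmol CYP2C9. All cells reproduce published values at their
printed precision except one: 0.6725 × 49.07 = 32.9996 → 33.00, whereas
the published \*1/\*2 cell reads 33.03 (and the rounded ratio 0.673
gives 33.02). That table is internally inconsistent at this single cell;
the corresponding test is deliberately left failing with an explanatory
message rather than loosened.

### Enzyme-contribution (fm) redistribution

Wild-type fm: CYP2B6 0.0024, CYP2C8 0.0154, CYP2C9 0.8084,
CYP2C19 0.0015, CYP3A4 0.1723 (remainder 0.0). For a genotype with PG
ratio `pg`, the CYP2C9 weight is multiplied by
`pg × abundance_multiplier` while other enzymes keep their weights, and
the vector is renormalised. With the default multiplier of 1
(activity-only scaling), \*2/\*2 gives fm(CYP2C9) ≈ 0.593 and \*3/\*3
≈ 0.273. Published population-simulator estimates for \*3/\*3 are lower
(~0.11) because they embed genotype-specific expression assumptions;
the `abundance_multiplier` argument exposes exactly that degree of
freedom without asserting a value for it.

### Clearance scaling

`scale_clearance(cl_wt, fm, pg, mode)` supports:

- `linear`: `CL(g) = CL_wt · (fm·pg + 1 − fm)` — pathway-proportional.
- `well-stirred`: invert the well-stirred model for the wild type, scale
  the CYP2C9 share of CL_int by `pg`, and run the model forward again.

For a low-extraction drug the two differ by ≈ `E_H·(1−s)` to first
order, where `E_H` is hepatic extraction and `s = fm·pg + 1 − fm` the
linear scale factor. The tests assert the difference ≤ `E_H` in general
and < 2% where `E_H ≈ 0.02`. A flat "<2% whenever `E_H < 0.05`" bound
does not hold (at `E_H = 0.041`, `pg = 0.089` the difference is ~3.1%).

## 2. Retrograde intrinsic-clearance allocation (`sippk.retrograde`)

Physiology defaults: hepatic blood flow Q = 97 L/h, liver 1650 g,
40 mg microsomal protein per g liver (MPPGL), body weight 70 kg,
blood-to-plasma ratio 1, CYP2C9 abundance 73 pmol/mg protein.

Convention: hepatic clearance is taken as `CL_H = CL/F · fa · fg`
(with fa = fg = 1 for siponimod this is CL/F itself), and the
well-stirred relation is inverted,

```
CL_int = CL_H · Q / (fu_B · (Q − CL_H)),   fu_B = fu / (B:P)
```

so that the forward computation recovers CL/F exactly (round-trip
relative error < 1e−9, property-tested over 1000 random draws). At
siponimod's extraction (~0.04) this convention differs from the
textbook oral relation `CL_po = fu·CL_int/(fa·fg)` by ~4%; the package
adopts the exactly-invertible form. `CL_H ≥ Q` raises
`NonInvertibleClearanceError` naming the blood-flow limit.

Total CL_int (L/h) is split across enzymes by fm; per-pmol values
follow by dividing by abundance × MPPGL × liver mass. With the default
physiology the CYP2C9 share back-calculates to 58.5 µL/min/pmol, within
~20% of the 49.07 anchor — the residual reflects the plasma-binding and
scaling-factor uncertainties typical of retrograde calculations.

## 3. PK engine (`sippk.pk`)

One-compartment, first-order absorption and elimination; concentrations
in ng/mL, amounts in mg, time in h. Each dose contributes a Bateman
term; arbitrary regimens are superposed (`Regimen.single/qd/bid/
repeated`, composable with `+`, shifting and scaling). The `ka = k`
degeneracy uses the analytic limit `C = F·D·ka·t·e^{−ka t}/V`.
Default grid: 0.25 h steps out to last dose + 10 elimination
half-lives.

`simulate_ode` integrates the same two-state system (gut, central) with
`scipy.integrate.solve_ivp` (LSODA, rtol 1e−9), restarting at dose
times (state jumps) and at user breakpoints; an `elimination_scale(t)`
callable multiplies CL, which is how time-varying inhibition enters.
The closed form and the ODE agree to < 0.1% (oracle test).

### NCA

AUC by the linear-up/log-down trapezoid. Terminal slope λz: among
suffix windows of the last ≤10 post-Tmax points (≥3 points), choose the
best log-linear R²; if the best R² < 0.8, t½ and AUC∞ are reported
undefined rather than extrapolated. `AUC_inf = AUC_last + C_last/λz`.
Baseline siponimod t½: ln 2 · (2.12 × 70)/4.0 ≈ 26 h.

## 4. Drug models (`sippk.drugs`, `sippk.io`)

`DrugModel` is a frozen, validated dataclass. Built-in YAML fixtures:

- **siponimod**: MW 516.6, ka 0.98 h⁻¹, V 2.12 L/kg, CL/F 4.01 L/h,
  fu 0.0002, fa = fg = 1, fm as above.
- **fluconazole**: MW 306.3, ka 2.0 h⁻¹, V 0.7 L/kg, CL/F 0.8 L/h,
  fu 0.9, Ki 20.4 µM (CYP2C9), 10 µM (CYP3A4).

YAML parsing is strict: unknown keys are rejected and units are checked
against the expected unit string per field (`SchemaError` otherwise).
Published per-genotype CL/F values (4.01 / 2.78 / 1.49 / 1.35 /
0.90 L/h) ship as `data/genotype_clf.csv` and are treated as inputs;
`genotype_scan` can alternatively derive clearances from the activity
table (`source="activity"`).

## 5. DDI prediction (`sippk.ddi`)

Unit conversion: `µM = (ng/mL) / MW`. Perpetrator steady state is
declared when the last dosing-interval AUC is within 2% of the previous
one (`NotAtSteadyStateError` otherwise); fluconazole 200 mg qd gives
Css,avg ≈ 34.0 µM.

- **Static**: `AUCR = 1 / (Σᵢ fmᵢ/(1+I/Kᵢ) + (1 − Σᵢ fmᵢ))` with I the
  chosen exposure metric (average by default; max/trough and
  total/unbound bases selectable via `InhibitionSpec`). CYP2C9-only:
  2.02; including CYP3A4: 2.77.
- **Dynamic**: the victim is re-simulated by ODE with
  `elimination_scale(t) = Σᵢ fmᵢ/(1+I(t)/Kᵢ) + (1 − Σᵢ fmᵢ)`, where
  `I(t)` is the closed-form perpetrator concentration. AUCR and Cmax
  ratio come from paired NCA on identical grids. Under a constant
  inhibitor the dynamic result matches the static formula to < 0.5%
  (consistency test).

## 6. In-vitro phenotyping (`sippk.phenotyping`)

`DonorBank` holds per-donor probe activities and reaction rates (≥3
donors). Correlation analysis uses Pearson r (`scipy.stats.pearsonr`);
an enzyme is "supported" as the major contributor at r > 0.7. Constant
columns are excluded with a warning. Genotyped incubations are compared
to wild type as `fold_decrease = mean(WT)/mean(g)` with Welch's t-test
(`scipy.stats.ttest_ind(equal_var=False)`). Published p-values for
n = 2 incubations are not reproducible from printed means/SDs and are
treated as context, not targets.

## 7. Synthetic data (`sippk.synth`)

Generators carry an explicit `GroundTruth` (fm vector, genotype
multipliers {1.0, 0.345, 0.089}, inter-donor CV 30%, replicate CV 10%,
seed). Donor activities are log-normal about 1; rates are
`Σ fmᵢ·activityᵢ` times log-normal replicate noise. Calibration tests:
over 200 seeds the correlation analysis identifies CYP2C9 ≥95% of the
time with 16 donors, and genotyped-incubation multiplier recovery is
within 2× the injected CV ≥90% of the time. The generators model only
what the analyses consume (no incubation kinetics, depletion, or
nonspecific binding).

## 8. Virtual populations (`sippk.population`)

Between-subject variability is log-normal with
`σ = √ln(1+CV²)`, applied to CL (and optionally V, ka) with the
geometric mean pinned to the base model value; fixed draw order makes
results reproducible per seed. Summaries report geometric mean,
geometric CV%, median and 5th/95th percentiles.

## 9. Numerical and design choices

- Deterministic core: the headline genotype fold-changes involve no
  random numbers; `scripts/acceptance.py` takes a seed only for
  interface uniformity.
- scipy/numpy/pandas are used for all standard numerics (integration,
  statistics, sampling, tabular IO); the modelling layer on top is
  original to this package.
- All file IO is plain text (YAML/CSV/JSON); fixtures are a few KB.

## 10. Limitations

- One-compartment disposition with optional peripheral compartment off
  by default; siponimod's distribution kinetics are simplified.
- The well-stirred model ignores transporters, extrahepatic clearance
  and active-metabolite feedback.
- Competitive, reversible inhibition only; no induction, no
  time-dependent inhibition.
- fm redistribution is activity-proportional unless an abundance
  multiplier is supplied; genotype-specific expression is not asserted.
- Synthetic in-vitro data are calibrated for the implemented analyses,
  not as a general microsome simulator.
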