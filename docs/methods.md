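# Methods

## Model structure and assumptions

The minimal PBPK model lumps a hamster into five compartments: an oral
absorption depot, blood, lung, trachea, and the rest of the body. Lung and
trachea are resolved because they are the target tissues for
respiratory-tract exposure; everything else is pooled. Distribution is
perfusion rate-limited: each tissue equilibrates instantaneously with the
blood perfusing it, with the tissue-to-blood ratio fixed by a partition
coefficient. This is appropriate for small lipophilic molecules and is the
regime reported for all three analytes (pyronaridine, artesunate,
dihydroartemisinin). Lung and trachea additionally exchange material
directly through first-order rate constants `k_lt` and `k_tl`,
representing airway transport between the two tissues.

Elimination is a single apparent oral clearance `CL/F` acting on blood.
In the parent–metabolite model every cleared mole of artesunate becomes a
mole of dihydroartemisinin in blood (artesunate is essentially completely
hydrolyzed to DHA in vivo), which is why the parent–metabolite model is
restricted to molar units: the conversion term `C_blood·CL/F` is only
mole-conserving when parent and metabolite amounts share a unit.

Two structural details deserve explicit notice:

- **Blood outflow exceeds cardiac output.** The blood equation removes
  `C_blood·(Q_co + Q_trachea + Q_rest)`, i.e. the lung receives the full
  cardiac output while the trachea and rest-of-body flows are additional
  rather than a partition of `Q_co`. We keep this exactly as the model was
  fitted: every outflow term has a matching tissue gain term, so the
  system is internally mass-conserving regardless.
- **The metabolite trachea equation has two forms.** The return (outflow)
  term of the metabolite trachea compartment can be written with the
  lung partition coefficient (`C_lung,m·Q_trachea/K_lung,m`, the
  `as_printed` form the source model used) or with the trachea's own
  coefficient (`C_trachea,m·Q_trachea/K_trachea,m`, the `mass_balanced`
  form). Only the latter cancels pairwise against the blood equation's
  trachea-return term; the printed form carries a balance residual
  `Q_trachea·(C_trachea,m/K_trachea,m − C_lung,m/K_lung,m)` in the
  metabolite total. A useful corollary of the printed form: summing its
  lung and trachea steady-state balances collapses the lung-to-blood AUC
  ratio to exactly `K_lung,m`. Both forms are implemented
  (`ModelSpec.metabolite_trachea_form`); `as_printed` is the default
  because it is the form behind the reported DHA tissue ratios. The
  mole-conservation property tests target the `mass_balanced` form and
  assert the exact residual for `as_printed`.

The metabolite trachea concentration is computed as
`A_trachea,m/V_trachea` (the parent amount would mix analytes in a
metabolite equation).

## Units and parameters

Canonical internal units: amounts in ng (pyronaridine) or nmol
(artesunate/DHA), volumes mL, time h, flows mL/h. Clearances are accepted
in L/h as tabulated and converted internally; reported concentrations are
ng/mL or nmol/L. Molar masses used for the mg→nmol dose conversion are
standard reference values (artesunate 384.42 g/mol, DHA 284.35 g/mol,
pyronaridine free base 518.05 g/mol) and can be overridden in the config.
Dose is interpreted as administered compound mass (mg/kg × body weight)
with no salt correction; an optional `salt_factor` multiplier is provided
since formulations are often salts.

Physiology (volumes, flows) is fixed; `V_rest`, `Q_rest` and optionally
`Q_trachea` (as 2.1% of cardiac output) are derived from the totals, and a
hand-specified full set is cross-checked to 1e-9 relative consistency.
The bundled configs carry the fitted hamster parameter sets for both
models.

## Numerical choices

The system is linear and time-invariant between dose events, so the
right-hand side is a constant matrix that doubles as the exact Jacobian.
Integration uses `scipy.integrate.solve_ivp` with LSODA by default,
`rtol = 1e-8`, `atol = 1e-10 ×` the per-dose amount, restarted at each
dose event with the dose added to the depot. The artesunate model is
severely stiff (blood turnover ≈3.5×10⁵ h⁻¹ from CL/F = 2517.7 L/h over
7.2 mL of blood); implicit methods handle it in milliseconds.

Output grids default to 0.1 h spacing (pyronaridine) and 0.02 h
(artesunate/DHA, whose ≈0.4 h half-life needs sub-hour resolution), with
40 log-spaced points appended after each dose event. The refinement
matters: the post-dose blood transient is effectively instantaneous, and
without it trapezoidal AUCs on the output grid miss ≈2% of the artesunate
blood exposure; with it the single-dose blood AUC matches the analytic
`dose/(CL/F)` to better than 0.1%. Tiny negative states (below 10× the
absolute tolerance) are clipped to zero; anything larger aborts with an
error.

Steady-state and AUC tissue-to-blood ratios have closed forms: integrating
the lung and trachea balances over a dosing interval at periodic steady
state (or over 0→∞ for a single dose) and setting the net change to zero
yields a 2×2 linear system in the ratios. These oracles are exact for the
linear model, reduce to `(K_lung, K_trachea)` when the exchange constants
vanish, and agree with long-run simulation to <0.5% — the main
integrator cross-check.

## Noncompartmental analysis

Linear trapezoidal AUC with interpolated window endpoints; C_max/T_max by
direct observation with ties broken toward the earliest time; terminal
slope by ordinary least squares on ln C vs t, requiring ≥3 positive
points, with `t_1/2 = ln 2 / k_e`. A nonnegative slope is flagged rather
than raised. The regression window defaults to everything after the final
dose plus 4 h (or after T_max when no dose information is given) and is
always recorded in the result, because the window materially affects the
estimate. Observed-style datasets are naive-pooled (arithmetic mean across
animals per time point) before NCA — with destructive sampling no animal
has a full profile, so subject-level estimation is not possible. BLQ
records enter pooled means as zero by default (configurable to drop).

Under the study parameters both artesunate and DHA show flip-flop
kinetics: elimination (`CL/F/V_blood`) is orders of magnitude faster than
absorption (`k_a = 1.74 h⁻¹`), so the terminal slope estimates the
absorption rate and the half-life tends to `ln 2 / 1.74 = 0.398 h`
regardless of the window placement in the tail.

## Fitting

Naive-pooled weighted least squares over all records, physiology fixed,
selected biochemical parameters estimated in log₁₀ space under bound
constraints (`scipy.optimize.least_squares`). Default weighting is
1/prediction²: concentrations span more than three orders of magnitude
across matrices and uniform weighting would let the lung dominate.
Multi-start (8 starts, log-uniform within bounds, seeded) is available
because the exchange constants can produce local minima; the recovery
studies in the test suite converge from a single generic start. A
post-fit flatness check perturbs each estimate two-fold and flags
parameters that move the objective by less than 1e-8 of the weighted data
scale as poorly identifiable — the pyronaridine `K_rest ≈ 5×10⁻⁷` regime,
where the rest-of-body return is effectively instantaneous, is the
canonical example. Simulation failures during optimization return a large
finite penalty so the optimizer survives hostile corners of parameter
space. Per-group fitting is the pipeline default, since dose groups in
this kind of study are often fitted separately.

## Sensitivity and validation

Normalized sensitivity coefficients use a forward one-sided perturbation
(default 1%, configurable): `NSC = ((A−B)/B)/((C−D)/D)`. Metrics are
blood C_max and blood AUC(0→last) from a single dose simulated on the
3-day grid; coefficients with magnitude above 1 are flagged as amplifying
input error. Because AUC(0→∞) = dose/(CL/F), the clearance coefficient has
the closed-form forward-difference value `((1/1.01)−1)/0.01 = −0.990`,
which the implementation reproduces — a built-in correctness anchor.

Fold error is prediction/observation; the average fold error is the
geometric mean `10^(Σ log₁₀ FE / n)`; the two-fold acceptance band is
closed (`[0.5, 2]` counts as within).

## Synthetic data

The generator reproduces the study design: two dose groups (180/360 mg/kg
pyronaridine or 60/120 mg/kg artesunate at the 0.10201 kg mean body
weight), three daily oral doses, the 22-point blood grid over 0–72 h and
the 13-point tissue grid, four animals per time point, destructive tissue
sampling (one animal id shared by the lung and trachea records at a time
point). Residual error is proportional lognormal with CV 20% by default,
mean-corrected (`obs = pred·exp(sZ − s²/2)`, `s² = ln(1+cv²)`) so the
expected observation equals the model prediction; additive and combined
error models are available. Predose records are exact zeros; an optional
LLOQ censors records below it (flagged, value withheld).

What the generator does **not** emulate: between-animal parameter
variability (all animals share one parameter set), assay calibration
structure, heteroscedasticity beyond the proportional model, and
tissue-homogenate dilution (tissue records are tissue-equivalent
concentrations as reported after bioanalytical correction). Passing
recovery tests therefore demonstrate estimator correctness under the
assumed error model, not robustness to population variability.

## Problem sizes used in the test suite

Simulations run on the default grids (≈3.4 k output points for a 14-day
pyronaridine regimen; ≈3.6 k for a 72 h artesunate run). The parameter
recovery study uses 20 replicate single-group datasets at 15% CV with four
free parameters and a single optimizer start each; the whole suite runs in
well under a minute on one core.

## Known limitations

- Absolute concentrations and AUCs for a specific dose group are only as
  good as the single shared parameter set; the source study's per-group
  absolute exposures are not dose-proportional and therefore imply
  group-specific fits that are not tabulated, so this package treats
  dimensionless ratios and half-lives as the reproducible quantities.
- The artesunate lung partition coefficient (10.33) is inconsistent with
  the reported artesunate lung-to-blood AUC ratio of 3.34; the model
  yields ≈10.3 from the tabulated value, and the analytic oracle shows no
  parameter set can give 3.34 with the remaining values fixed. The
  tabulated parameter is used as given.
- Similarly, the reported DHA trachea-to-blood AUC ratio (0.15) is not
  reproduced by either trachea form (0.136 as printed, 1.06
  mass-balanced).
- No lag time, transit absorption, IV routes, enterohepatic
  recirculation, protein-binding submodels, or interspecies scaling.
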