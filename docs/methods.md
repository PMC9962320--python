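# Methods

This note documents the models, conventions and numerical choices behind
`mtxpk`, and what the synthetic-data results do and do not establish.

## The model catalog

Each of the six published pediatric MTX PopPK models is carried as a
declarative specification: structural model (2- or 3-compartment
mammillary), covariate formulas producing the typical parameter values,
per-parameter inter-individual variability (IIV, random effect η),
inter-occasion variability (IOV, random effect κ; clearance of the Hui
model only), and a residual error model with proportional and/or additive
components.  Covariate formulas are stored as text expressions evaluated
by a restricted AST interpreter (arithmetic, comparisons, `where(...)`
branches and a handful of math functions), which keeps the catalog fully
YAML-serializable: a user can add or modify a model without touching code.

Conventions and choices where the sources were ambiguous or silent:

* **Units.** Clearances L/h, volumes L, micro rate constants 1/h,
  concentrations µmol/L, amounts µmol (methotrexate molar mass
  454.44 g/mol, so 1 mg = 2.2005 µmol).  Serum creatinine is carried in
  both mg/dL and µmol/L (×88.42); the Gao clearance covariate
  `(Scr − 26) × (−0.0097)` is only dimensionally sensible in µmol/L, so
  that field feeds it.
* **IIV/IOV magnitude.** Reported CV percentages are interpreted as the
  standard deviation of the log-normal random effect, ω = CV/100.  Several
  reported CVs exceed 100% (up to 137.6%), for which the exact
  ln(1 + CV²) convention and the approximate one diverge badly; the
  approximate convention is the only self-consistent reading of values
  that large and is the package default.  The exact convention remains
  selectable (`omega_matrix(..., convention="lognormal")`).
* **Individual parameters.** `typical × exp(η + κ)` uniformly; parameters
  without a listed random effect stay at their typical values.  Realized
  parameters must be strictly positive — a non-positive value (possible
  for Gao's linear creatinine term at very high creatinine) raises, and
  the MAP objective treats it as an infeasible trial point.
* **Hui renal term.** The printed form "(eGFR × 1.73/192 × BSA)^0.256"
  is ambiguous.  Default reading: absolute glomerular filtration rate
  normalized to 192 mL/min, `((eGFR × BSA / 1.73) / 192)^0.256` — the
  physiological interpretation (eGFR is indexed to 1.73 m²).  The literal
  left-to-right reading is available via
  `build_model_catalog(hui_renal="literal")`.
* **Zhang gender coding.** Gender = 1 for girls (default): the negative
  coefficient then lowers clearance for the minority-female development
  cohort.  Configurable (`zhang_gender_coding="male=1"`).
* **Zhang alkalinization volume (OH).** The additive `(OH/100)^0.514`
  clearance term needs a covariate that real validation datasets rarely
  record and whose development-cohort central value is not available, so
  the model has no default: users must supply one
  (`covariate_defaults`), and the synthetic cohort generates OH directly.
* **Aumente age branch.** Age exactly 10 years uses the "> 10 years"
  equations.
* **Jonsson residual error.** Not reported in the source; a 30%
  proportional error is assumed.
* **Gao IIV placement.** The source tables disagree about whether the
  second IIV sits on V1 or V2; the structural equations mark η on V2, and
  η placement defines the model, so IIV is on CL (17.9%) and V2 (26.2%).
* **BSA.** When not recorded, Mosteller √(height × weight / 3600) by
  default; DuBois available.
* **Missing covariates.** Filled from the development population's
  published central values where available; a covariate that is neither
  recorded nor defaulted raises an error naming the model and covariate.

## Infusion kinetics

Dosing is a set of constant-rate infusion events (each HD-MTX course is
two events: 10% of the dose over 0.5 h, then 90% over 23.5 h).  Within
any interval where the input rate and parameters are constant, the linear
system dA/dt = M·A + b has the exact solution
A(t+Δt) = E·A(t) + (E − I)·M⁻¹·b with E = expm(M·Δt), so profiles are
propagated segment by segment across the breakpoints formed by event
boundaries, occasion boundaries and query times.  This is exact for the
linear model (no step-size error), handles the 3-compartment Gao model,
overlapping events and per-occasion parameter changes (Hui IOV) uniformly,
and is the reason a closed-form macro-constant solution was not used.
Query times falling on a boundary take the left segment's endpoint state;
the state is continuous there, so the choice only fixes bookkeeping.

An independent verification path (`ode_reference`) integrates the same
system with SciPy's adaptive LSODA at rtol 1e-10 per segment.  The two
solvers agree to better than 1e-6 relative on randomized 2- and
3-compartment parameter draws (part of the acceptance suite); dose
linearity, time-shift equivariance, superposition and mass balance are
tested as properties.

## MAP-Bayesian estimation

With the population model fixed, a patient's random effects are estimated
at the posterior mode by minimizing

    obj(η, κ) = Σ_i [ ln(2π σ_i²) + (y_i − f_i(η, κ))² / σ_i² ]
              + ηᵀ Ω⁻¹ η + Σ_occ κᵀ Ω_IOV⁻¹ κ,

where f_i is the model prediction at observation time t_i and
σ_i² = (prop · f_i)² + add² is the residual variance evaluated at the
individual prediction (standard posthoc behavior; no first-order
linearization anywhere).  Notes:

* Below-quantification-limit observations (< 0.05 µmol/L) are excluded
  from the objective and from all metrics; no M3-style censored
  likelihood is attempted, matching an evaluation that reports quantified
  samples only.
* κ is estimated only for occasions that carry usable observations;
  others stay 0.
* Optimization: BFGS from the prior mode plus four jittered restarts
  (jitter SD 0.5, seeded) — five starts total, guarding against local
  minima that the very large ω of the Zhang and Jonsson models can
  create.  Gradient tolerance 1e-8.  Infeasible trial points (overflowed
  matrix exponentials, non-positive parameters, vanishing residual
  variance) receive a large finite penalty inside the optimizer and are
  reported as +∞ by the public objective.  The returned estimate is never
  worse than the prior mode; with no usable observations the prior mode
  (η = 0) is returned directly, as the objective then reduces to the
  prior term.
* Because σ² depends on f under a proportional error model, the ln σ²
  term shifts the optimum slightly away from η = 0 even when an
  observation equals the typical prediction exactly; the exact
  "residual variance → ∞ ⇒ η̂ → 0" shrinkage limit holds for additive
  error models (variance independent of the prediction), and the tests
  check both facts in that form.
* Correctness is established against a two-stage grid-search oracle
  (coarse sweep of [−3, 3] per dimension, then a ≤1e-3-step refinement
  around the coarse minimum) on 1- and 2-η problems, and by recovery of
  known η from rich, low-noise simulated patients (|η̂ − η| < 0.05).

## Evaluation statistics

PE_i = (C_i,pred − C_obs)/C_obs × 100%, computed once, in percent, for
population (PRED, η = 0) and individual (IPRED, η̂) predictions at the
recorded sampling times.  Summaries: median PE, MPE = mean(PE),
RMSE = √(mean(PE²)).  RMSE ≥ |MPE| (Jensen) is asserted on every summary.
Acceptance flags: bias acceptable iff |median PE| < 20% **and**
|MPE| < 20% (strict); precision acceptable iff RMSE ≤ 30% (inclusive).
Bland–Altman limits are mean(PE) ± 1.96 × sample SD(PE); the reference
axis is the mean of observation and prediction by default (the
conventional choice; the source figures specify only the error axis), and
can be switched to the observed concentration.

Patients whose MAP step fails are excluded from the IPRED summary with a
logged and reported count, and retained in the PRED summary.  Summaries
are invariant to patient order, and each patient's optimizer substream is
derived from the base seed plus the patient index, so evaluations are
deterministic end to end.

## The synthetic cohort generator

The generator emulates the *design* of a single-center pediatric ALL TDM
dataset: 51 patients, ages 1–13 y, median weight 19 kg / height 113 cm /
BSA 0.77 m² / creatinine 0.31 mg/dL, 40/51 male, doses of 1–5 g/m²
assigned by risk group (3 g/m² low-risk, 5 g/m² intermediate/high),
samples at ~24/48/72/96 h per course with Normal(0, 1 h) timing jitter
truncated at ±3 h, assay LLOQ 0.05 µmol/L, and follow-up per course
ending at the first concentration below 0.1 µmol/L.  Under these defaults
a cohort yields on the order of 300–360 observations over two courses per
patient (two chosen as a round default consistent with ~7 observations
per patient; per-patient course counts of the emulated dataset are
unknown), and the 24-h concentrations under typical parameters sit in the
clinically expected tens of µmol/L.

Covariates are sampled jointly, not as independent marginals: age is
log-uniform on its range, height and weight follow a packaged synthetic
growth-anchor table (median weight/height by age, loosely following
published pediatric growth medians) with multiplicative noise, BSA is
Mosteller-consistent by construction, and eGFR derives from height and
creatinine via Bedside Schwartz.  Because the log-uniform age marginal
has its median at the geometric mean of the range (≈3.6 y), the growth
curves are rescaled so that the *cohort* medians land on the configured
weight/height medians; the cohort therefore runs slightly heavy-for-age,
a deliberate trade that preserves both the age range and the target
medians.  Out-of-range body sizes are clipped; a clipped BSA re-derives
weight so the BSA-formula invariant survives.  The alkalinization volume
OH is generated log-normally with median 200 mL (range 100–400 mL), a
plausible pediatric alkalinization-fluid volume contributing ~1.4 L/h to
the Zhang clearance.

All randomness flows through one seed; each patient uses substreams
derived from (seed, patient index), so cohorts are bitwise reproducible
and insensitive to generation order.  Ground-truth η/κ are kept next to
each simulated patient and stripped by `make_validation_like_dataset`,
whose output is structurally identical to what the dataset reader
produces.

What passing tests on synthetic cohorts shows — and does not.  The
generator exercises the pipeline under a *known* data-generating model:
self-consistency (a model evaluated on its own cohorts has nearly
unbiased IPRED and IPRED-RMSE at or below PRED-RMSE) and cross-model
contrast (a weight-only model forecasting a cohort generated with strong
body-size covariates pays a large population-prediction penalty) are
internal-validity checks of the machinery.  They do not certify any
model's accuracy on real patients: real TDM data carry covariate
measurement error, model misspecification shared by all six models,
nonlinear elimination at high doses, and record-keeping noise that the
generator deliberately omits.

## Problem sizes and runtime choices

The solver cross-check uses 200 randomized parameter draws; the pipeline
self-consistency check uses 51-patient cohorts over 5 seeds (majority
criterion on the per-seed outcomes); grid oracles refine to 1e-3 steps.
These sizes make the full suite run in a few minutes on one core while
leaving each check statistically comfortable.

## Known limitations

* No nonlinear (saturable) elimination, absorption or 7-OH-MTX metabolite
  kinetics; all models are linear mammillary systems.
* No censored-likelihood (M3) handling of BLQ data.
* No population re-estimation, no uncertainty on η̂ (no FIM), no dose
  optimization.
* MAP multi-start is a heuristic; with extremely large ω (Zhang Q at
  137.6% CV) distinct local minima can in principle survive five starts.
* The evaluation emulated here cannot be reproduced quantitatively
  without the original clinical dataset, which is not public; the
  package's claims are therefore about the machinery, established on
  printed reference values and simulated data.
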