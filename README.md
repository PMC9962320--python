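# mtxpk

Forecasting and external evaluation of population-pharmacokinetic (PopPK)
models of **high-dose methotrexate (HD-MTX)** in children with acute
lymphoid leukemia (ALL).

HD-MTX (>1 g/m², given as a 24-h infusion: 10% of the dose over 0.5 h,
90% over 23.5 h) has a narrow therapeutic window and large between-patient
variability, so dosing is guided by therapeutic drug monitoring (TDM) and,
increasingly, by model-informed precision dosing: a PopPK model plus a
patient's own measured concentrations yields individualized forecasts.
Before a published model can be trusted for that, its predictive
performance must be checked on patients it was not built on.  `mtxpk`
packages everything needed to run such an external evaluation:

* **Model catalog** (`mtxpk.models`) — six published pediatric MTX PopPK
  models (Aumente, Gao, Hui, Medellin-Garibay, Zhang, Jonsson) as
  declarative, YAML-serializable specifications: 2- or 3-compartment
  structure, covariate formulas for the typical parameters, log-normal
  inter-individual (η) and inter-occasion (κ) variability, and residual
  error; plus the Bedside Schwartz eGFR (`0.413 × height / Scr`) and BSA
  helpers.
* **PK engine** (`mtxpk.pk`) — exact piecewise matrix-exponential solution
  of linear mammillary compartment models under arbitrary constant-rate
  infusion schedules, with an independent adaptive-ODE reference solver
  used for verification.
* **MAP-Bayesian forecasting** (`mtxpk.bayes`) — posterior-mode estimation
  of each patient's random effects given their concentrations (the
  "posthoc" step of nonlinear mixed-effects software), producing population
  predictions PRED (η = 0) and individual predictions IPRED (η at the MAP
  estimate).
* **Evaluation statistics** (`mtxpk.evaluation`) — relative prediction
  error PE = (C_pred − C_obs)/C_obs × 100%, its median, mean (MPE) and root
  mean square (RMSE), acceptance flags (|median PE| and |MPE| < 20%,
  RMSE ≤ 30%), Bland–Altman limits of agreement, and the full
  model × {PRED, IPRED} evaluation pipeline.
* **Synthetic cohorts** (`mtxpk.cohort`) — a seeded generator of virtual
  pediatric ALL TDM datasets (correlated covariates, risk-group dosing,
  ~24-hourly sampling with timing jitter, assay noise, 0.05 µmol/L
  quantification limit, follow-up until < 0.1 µmol/L) with ground-truth
  random effects retained for recovery tests.
* **I/O and CLI** (`mtxpk.io`, `mtxpk.cli`) — a flat CSV event-record
  dialect and a thin `mtxpk catalog | simulate | evaluate` command line.

## Worked example

```python
from mtxpk import (CohortConfig, OptimizerConfig, evaluate_models,
                   get_model, make_validation_like_dataset)

config = CohortConfig(seed=2023, n_patients=20, model_name="medellin")
dataset = make_validation_like_dataset(config)
report = evaluate_models([get_model("medellin"), get_model("jonsson")],
                         dataset, OptimizerConfig(seed=0))
print(report.summary_frame().to_string(index=False))
```

prints (89 quantifiable concentrations from 20 virtual patients):

```
   model prediction  n  median_pe_pct  mpe_pct  rmse_pct  acceptable_bias  acceptable_precision
medellin       PRED 89          -2.90     2.25     58.61             True                 False
medellin      IPRED 89          -1.98     2.96     20.75             True                  True
 jonsson       PRED 89         515.15   724.12   1049.17            False                 False
 jonsson      IPRED 89          -6.74     8.07     51.09             True                 False
```

The cohort was generated by the Medellin-Garibay model, so that model's
individual predictions are nearly unbiased and precise.  The Jonsson model
scales only with body weight and carries a much lower typical clearance,
so its population predictions overshoot the observations by several
hundred percent — until each patient's own samples are folded in (IPRED),
which removes most of the bias.  This is the characteristic signature of a
covariate-poor model under external evaluation.

The scripts in `examples/` walk through each capability: catalog
inspection, profile simulation, MAP forecasting for a single patient, and
the evaluation pipeline above.

## Scope

The package deliberately re-implements only the evaluation machinery: it
does not re-estimate any model's parameters, model nonlinear elimination
or the 7-OH-MTX metabolite, or optimize doses.  See `docs/methods.md` for
the modeling choices, conventions and limitations.
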