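# damicox

Delta-adjusted multiple imputation (DA-MI) sensitivity analysis for Cox
proportional-hazards models with a **missing time-varying covariate**.

## The problem

Longitudinal cohorts routinely lose biomarker measurements — missed visits,
unrecorded labs, dropout. When a time-varying covariate such as alkaline
phosphatase enters a Cox model

λ(t | x) = λ₀(t) · exp(β₁·Age + β₂·Gleason + β₃·BMI + β₄·PSA + β₅·Drug + β₆·AlkPhos(t)),

complete-case analysis (CCA) is valid only under MCAR, and multiple
imputation (MI) only under MAR. If missingness depends on the unobserved
values themselves (MNAR), no analysis of the observed data alone can be
validated — the honest option is a **sensitivity analysis**: impute under
MAR, then perturb the imputed values by an offset δ,

Y_ij = β₀ + β₁·X_ij + δ·(1 − r_ij) + u₀j + ε_ij,

where r_ij = 1 for observed cells, and refit over a grid of δ (default
−2, −1, 0, 1, 2 in log-biomarker units; δ = 0 is the MAR anchor). If the
pooled hazard ratios are stable across δ, the MAR conclusion is robust; a
significance reversal at some δ is a tipping point.

`damicox` implements the full loop for biostatisticians and trialists:

- **panel data**: long-format container with per-cell missingness, CSV I/O,
  counting-process (start, stop] conversion with LOCF, missingness and
  Table-1-style group-comparison summaries;
- **survival core**: Kaplan–Meier, Nelson–Aalen, a Newton–Raphson
  counting-process Cox fitter (Efron/Breslow ties, Breslow baseline),
  Grambsch–Therneau proportional-hazards test on scaled Schoenfeld
  residuals, covariate-adjusted survival curves;
- **imputation**: Bayesian normal regression on the log scale (optional
  per-subject random intercept) with survival-aware predictors — event
  indicator, Nelson–Aalen cumulative hazard at the subject's own time, and
  record-level interval variants for time-varying targets — m chains with
  iteration traces;
- **delta adjustment**: shift imputed cells only, on the log or original
  scale, over a grid;
- **pooling**: Rubin's rules with Barnard–Rubin degrees of freedom;
- **pipeline**: CCA / MI / DA-MI analyses, Table-2- and Table-3-shaped
  outputs, robustness summary with tipping-point flags;
- **synthetic cohorts**: prostate-like generator (random-intercept/slope
  log-biomarker trajectories, bimodal age, categorical Gleason/treatment,
  piecewise-exponential event times, MCAR/MAR/MNAR mechanisms) so every
  stage is testable without any clinical download.

## Worked example

```python
import damicox as dx

# a prostate-like cohort: 1,504 subjects, ~64% events, median ~8 months,
# ~62% of the alkaline-phosphatase records missing under MAR
data = dx.simulate_cohort(dx.preset_prostate_like(), seed=7,
                          missingness=dx.preset_missingness())
print(dx.cohort_summary(data))
print(dx.missingness_summary(data, "alk_phos"))

cfg = dx.AnalysisConfig(seed=7)          # m=5 imputations, grid -2..2
mar = dx.run_mar_analysis(data, cfg)     # Table-2 shape
sweep = dx.run_delta_sweep(data, cfg, stack=mar.stack)  # Table-3 shape
print(sweep.pivot())
print(dx.robustness_summary(sweep))
```

prints (abridged):

```
CohortSummary(n_subjects=1504, n_records=5619, n_events=997,
              event_percent=66.3, median_time_to_event=7.91, ...)
MissingnessReport(variable='alk_phos', n_observed=2097, n_missing=3522,
                  percent_missing=62.7, n_subjects_complete=157)

                          -2                   ...  2
alk_phos                  1.001 (1.001; 1.002) ...  1.000 (1.000; 1.000)
gleason=3+3               0.578 (0.450; 0.741) ...  0.576 (0.448; 0.740)
drug=prostatectomy+EBRT   1.596 (1.201; 2.120) ...  1.560 (1.174; 2.073)

                 hr_mar  max_rel_hr_change  significance_reversal
alk_phos          1.001              0.001                  False
gleason=4+4       0.816              0.004                   True
```

Each sensitivity-table cell is the Rubin-pooled hazard ratio with its 95%
CI after shifting the imputed log-biomarker values by that column's δ; the
δ = 0 column is exactly the MAR analysis (same imputation stack). The
robustness summary reports, per covariate, the largest relative HR change
against the MAR column and flags covariates whose CI excludes 1 at some δ
but not others.

A thin CLI wraps the same functions:

```sh
damicox simulate --n 1504 --seed 7 --missing mar --out cohort.csv
damicox describe cohort.csv --out table1.csv
damicox analyze cohort.csv --seed 7 --out pooled.csv
damicox sweep cohort.csv --seed 7 --deltas="-2,-1,0,1,2" --out sweep/
```

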