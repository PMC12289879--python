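# Methods

## Data model

A cohort is a long-format table: one row per subject-visit, with the
subject's event/censoring time `T` and event indicator repeated on every
row, baseline covariates constant within subject, and time-varying
biomarkers that may be missing. Missingness is identified with NaN, so the
mask r_ij (1 = observed) can never disagree with the values. Invariants
enforced on construction: every visit time ≤ T, event data constant within
subject, at least one visit per subject, non-negative times.

For Cox fitting the panel is converted to counting-process form: per
subject, half-open risk intervals (t_k, t_{k+1}] between consecutive
visits, the last ending at T where the event flag (if any) sits. Covariate
values are carried forward from the visit opening each interval (LOCF);
no other interpolation is offered, and the synthetic generator uses the
same convention so that generation and analysis agree about what "the
covariate value during an interval" means. A visit falling exactly at T
opens no interval; its event flag moves to the preceding interval.

## Survival core

Kaplan–Meier and Nelson–Aalen use the plain product-limit and d/n
conventions at distinct event times (no tie smoothing), because the
Nelson–Aalen step function is also evaluated at each subject's own time as
an imputation predictor and the two uses must agree.

The Cox fitter maximises the counting-process partial likelihood by
Newton–Raphson: start at β = 0, step-halving when a step would decrease
the log likelihood, convergence when the relative change falls below
1e−9, at most 100 iterations. Ties use the Efron correction by default
(Breslow by flag); with distinct event times the two coincide exactly.
Standard errors come from the inverse observed information; hazard ratios
and 95% CIs are exponentiated Wald intervals on the coefficient scale.
The baseline cumulative hazard is the Breslow estimator at β̂, which at
β = 0 reduces to Nelson–Aalen. A coefficient exceeding 15 in absolute
value flags likely monotone likelihood instead of diverging silently.
Risk-set sums are computed with suffix cumulative sums over stop- and
start-sorted orders, so one likelihood evaluation is O(n·p²) rather than
O(events · n · p²); a 1,500-subject, 14-column fit takes well under a
second.

The proportional-hazards check is the Grambsch–Therneau score test:
scaled Schoenfeld residuals regressed against a transform of event time
(identity by default; rank and Kaplan–Meier transforms available). The
implementation reproduces lifelines' `proportional_hazard_test` p-values
to numerical precision on shared data. On heavy-tailed time distributions
the identity transform is conservative (empirical size ≈ 0.02 at nominal
0.05); the km transform is close to nominal (≈ 0.05), which is why the
calibration study in `studies.py` uses it.

## Imputation under MAR

A single incomplete, positive, time-varying biomarker is imputed on the
log scale with a Bayesian normal linear model and a noninformative prior:
draw σ² from its scaled inverse chi-square, coefficients from their
normal given σ², then missing values from the predictive normal; back-
transform by exponentiation. Each of the m chains (default m = 5) repeats
the draw for a configurable number of iterations (default 20) with a
per-iteration trace of the imputed-value mean and SD. With one incomplete
variable the conditional model does not depend on previous imputations,
so iterations are independent redraws; the chain structure is kept for
trace diagnostics and parity with multi-variable chained equations. The
trace diagnostic flags non-mixing when the between-chain variance of
final-quarter means exceeds three times the average within-chain
variance.

An optional per-subject random intercept (grouping = subject, i.e.
repeated measures within patient) is estimated by REML via statsmodels
MixedLM; draws perturb the variance components by chi-square
approximations to their sampling distributions, draw fixed effects from
their normal, and draw each subject's intercept from its conditional
normal given that subject's observed residuals (prior for subjects with
nothing observed). The fixed-effects engine is the default.

### Survival-aware predictors

To keep the imputation model compatible with a proportional-hazards
analysis model, the predictor set includes outcome summaries: the event
indicator, the Nelson–Aalen cumulative hazard Ĥ(T_j) at the subject's own
event/censoring time, and optionally log T. For a **time-varying** target
these subject-level summaries are not enough: the risk information about
the cell at visit k accrues while that cell's value drives the hazard,
i.e. over (t_k, t_{k+1}]. The package therefore also derives record-level
predictors — an interval event flag (did the subject's event fall in this
record's interval) and the Nelson–Aalen increment across the interval —
and includes them by default. In pipeline recovery simulations (n = 500,
30% MAR, β = −0.3, 100 replicates) the subject-level set alone leaves an
attenuation bias of about 0.03; adding the interval predictors removes it
(bias 0.003 ± 0.010).

Observed entries are never modified; identical (data, spec, seed) gives a
bitwise-identical stack. One master seed spawns independent per-chain
substreams.

## Delta adjustment

`apply_delta` shifts **imputed cells only**. The default mode adds δ on
the log scale, i.e. multiplies the original-scale value by e^δ — the
reading that reconciles "multiply by a constant" with an additive
pattern-mixture offset, and the scale on which the default grid
(−2, −1, 0, 1, 2) is expressed. Additive and multiplicative original-
scale modes are available (with positivity checks), as is a per-record δ
hook for individual-level departures, and a helper that suggests a grid
{−2s, −s, 0, s, 2s} from the SD of the observed log values. Additive
modes compose: applying a then b equals applying a + b.

## Pooling

Per-imputation coefficients are pooled on the log-HR scale with Rubin's
rules (Q̄, W, B, T = W + (1 + 1/m)B) and Barnard–Rubin small-sample
degrees of freedom, with complete-data df taken as n_subjects − k. CIs
and p-values use the t reference with those df; HRs and CI bounds are
exponentiated afterwards. Pooling on the HR scale itself would violate
the approximate normality Rubin's rules require.

## Pipeline

`fit_cca` restricts to subjects with the target observed at every visit
(valid under MCAR); `run_mar_analysis` chains augment → impute → convert
→ fit → pool; `run_delta_sweep` reuses **one** MAR imputation stack across
the δ grid (adjust-then-analyze), so the δ = 0 column equals the MAR
analysis bitwise and the sweep isolates the δ effect from imputation
noise. Categorical covariates are reference-coded (defaults: Gleason 9,
EBRT). `robustness_summary` reports each covariate's maximal relative HR
change against the MAR column and flags significance reversals (the
tipping-point signal). A `log_covariates` option lets a biomarker enter
the Cox design as its natural log.

## Synthetic cohorts

The generator draws baseline covariates (two-component normal mixture for
age, normal BMI, categorical Gleason/treatment), per-subject linear
log-biomarker trajectories with random intercepts and slopes (intercepts
correlated with age so the biomarker is predictable from baselines), a
log-scale PSA process, and event times from λ₀·exp(βᵀx(t)) with the
hazard constant between scheduled visits — interval-wise exponential
inversion on the visit grid, matching the LOCF analysis convention.
Administrative censoring truncates follow-up; visits after the event are
dropped.

Missingness mechanisms: MCAR (coin flip), MAR (logistic on observed
columns and visit time), MNAR (logistic that may include the current log
value — the selection variant — and/or a pattern-mixture log-scale shift
added to the to-be-missing cells **before** event times are generated, so
the hazard is consistent with the shifted truth and the generative shift
is directly interpretable against the analysis δ). Mechanisms can act per
record or blank whole subjects (`unit="subject"`); the subject variant
uses each subject's first-visit covariates.

`preset_prostate_like()` is calibrated once, by simulation, to the four
summary statistics the applied example prints: 1,504 subjects, event
fraction near 63.8%, median time to event near 8 months, and (with
`preset_missingness()`) about 61.6% of biomarker records missing. The
real visit layout is unpublished; the preset assumes a quarterly schedule
(0, 3, 6, 9, 12 months) with administrative censoring at 14 months, which
reproduces the printed record-count scale (≈3.3 visits/subject). Because
the spec'd constant baseline hazard cannot jointly hit the event fraction
and the early median under administrative censoring alone, the preset
gives the log-biomarker trajectory a positive slope (0.125/month) and a
positive hazard coefficient so the hazard ramps over follow-up
(λ₀ = 0.020/month). The preset makes no attempt to reproduce the real
cohort's joint covariate distribution or its published hazard ratios.

## Validation studies (`damicox.studies`)

All studies run from a single seed with named substreams and are shared
by the test suite and `scripts/acceptance.py`. Problem sizes were chosen
to keep the whole battery at about a minute on one core.

- **MAR recovery** — n = 500, quarterly visits, β_alk = −0.3 on the raw
  biomarker, ~30% record-level MAR (driven by visit time and age),
  m = 5, 100 replicates: the pooled log HR must sit within 2 Monte-Carlo
  SE of the truth, and the δ = 0 sweep column must equal the MAR table
  bitwise.
- **Mechanism separation** — subject-level missingness, 60 paired
  replicates. Under MCAR, CCA is unbiased (subject-level masking is
  essential: record-level MCAR selects complete subjects by visit count,
  which correlates with event time and biases CCA for reasons unrelated
  to the estimator). Under follow-up-time-driven MAR (an observed-data
  mechanism), CCA's length-biased selection fails (bias ≈ 0.09) while MI,
  conditioning on time summaries, does not (≈ 0.00); the check is
  |bias_CCA| > |bias_MI|.
- **MNAR tracking** — pattern-mixture MNAR with shift s ∈ {−1, +1} on 60%
  of records, biomarker effect on the log scale, 80 replicates: the δ = s
  column must minimise |pooled β̂ − β_true| over the grid. Two design
  choices matter. First, the hazard is log-linear in the biomarker so the
  generative shift and the analysis δ share units; with a raw-scale
  effect, e^δ rescales the imputation noise as well as the mean and the
  best δ is no longer s. Second, the imputation uses the subject-level
  survival predictors only: the record-level interval predictors are
  informative enough to absorb most of the shift through the outcome
  channel, leaving all δ columns nearly identical — a sensitivity
  analysis is premised on the MAR model *not* being rich enough to
  explain the NMAR departure.
- **PH test size** — exact-PH exponential data, n = 150, 500 replicates,
  km transform: empirical size within Monte-Carlo error of 5%.
- **Estimator agreement** — n = 5,000 censored exponential data:
  max |−log S_KM − Ĥ_NA| < 0.01.

## What the synthetic studies do and do not show

The generator matches the structure the method assumes: linear log-
trajectories, proportional hazards given the current value, missingness
mechanisms of known type. Passing these studies shows the pipeline is
internally consistent and recovers truth *when its assumptions hold*. It
does not show robustness to trajectory nonlinearity, informative visit
timing, measurement error in observed values, or multivariate
missingness — none of which the generator produces. The published
clinical hazard-ratio tables are not reproduction targets: the underlying
dataset is not public, so numeric agreement with them is out of scope by
construction.

## Numerical and degenerate-input conventions

Collinear Cox designs raise an error naming the dependent columns;
imputation requires ≥ 10 observed target values and ≥ 2 imputations;
pooling with B = 0 falls back to the observed-data degrees of freedom;
empty survival inputs, unknown variables, non-positive values under a log
transform, probabilities outside [0, 1] after a logistic, and δ
adjustments that would produce non-positive biomarkers all raise with
specific messages. Zero-length risk intervals are dropped with the event
flag reassigned to the preceding interval.
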