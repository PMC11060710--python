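# Methods

## The phenotypic-age clock

PhenoAge is a two-stage Gompertz proportional-hazards construction. Stage
one scores mortality risk: with hazard `h(t|x) = b·e^{γt}·e^{β·x}`, the
probability of death within a horizon of 120 months is
`M = 1 - exp(-e^{xb}·(e^{120γ}-1)/γ)`, where `xb = ln b + β·x` collapses the
baseline scale and the covariate effects of age plus nine blood biomarkers
into one linear predictor. Stage two maps `M` back to years through the
*age-only* version of the same model, asking "at what chronological age
would the average person carry this mortality score?"; with published
constants that inversion is `PhenoAge = 141.50 + ln(-0.00553·ln(1-M))/0.09165`.

The printed constants satisfy an exact identity: since
`ln(-ln(1-M)) = xb + ln((e^{120γ}-1)/γ)`,

    PhenoAge = 141.50 + (xb + k)/0.09165,
    k = ln(0.00553·(e^{120·0.0076927}-1)/0.0076927)

The implementation evaluates this affine form everywhere. The two-step form
underflows in float64 once `M` rounds to 0 or 1 (which happens inside the
plausible clinical range, near xb ≈ -1); the affine form is exact, monotone
and total. The test suite verifies agreement with the literal two-step
evaluation at 13,000-digit precision to 1e-10 over xb ∈ [-30, 5], and that
`e^{120·0.0076927} - 1 = 1.51714` to 5 significant figures.

The coefficient set is treated as a calibrated black box: the inner horizon
is expressed in months while age enters in years, and we deliberately make
no attempt to re-derive or "fix" the unit mixture — the constants are only
ever used together.

Units are fixed (albumin g/L, creatinine µmol/L, glucose mmol/L, CRP mg/dL
with natural log, lymphocyte %, MCV fL, RDW %, ALP U/L, WBC 10³/µL). A
mg/L→mg/dL CRP converter is provided but never applied implicitly; unit
drift is the dominant wrong-answer risk for this clock.

**Winsorization.** Biomarkers are capped at their 1st/99th percentiles
(numpy type-7 quantiles) before scoring, pooling the sexes by default; the
field does not standardize whether capping happens before or after sex
stratification or whether CRP is capped on the raw or log scale, so both
are keyword options (`by_sex`, `log_scale_crp`) with the pooled/raw default
documented here. At symmetric percentiles the raw- and log-scale CRP caps
coincide.

**PhenoAgeAccel** is the residual from OLS of PhenoAge on chronological age,
fitted on the analysis sample with sexes pooled (one residual definition,
reported by sex). Residuals have mean zero and zero covariance with age by
construction; the fit is exposed for sex-specific use.

## Retraining the clock

`retrain_phenoage` refits both stages on any cohort with mortality
follow-up: a multivariable Gompertz-PH maximum-likelihood fit of death on
the nine biomarkers (ln CRP) and age defines the new `xb` (the fitted log
baseline rate becomes the intercept), and a univariate age-only fit supplies
the score-to-years mapping (`c2` = age slope; `c1` and the outer offset from
its shape and scale). The optimizer works on (log b, γ, β) — the log
parameterization enforces b > 0 — with the analytic gradient, BFGS followed
by Newton polishing, and declares convergence only below gradient norm 1e-6;
covariates are standardized internally (an exact reparameterization) for
conditioning. Standard errors come from the observed information
(central-difference Hessian of the analytic gradient). Retrained sets carry
their horizon in years; published and retrained sets are interchangeable
everywhere because only the (γ, horizon) pair's internal consistency
matters.

No installed Python package fits Gompertz proportional hazards with
covariates, so this likelihood is implemented directly; it is validated by
parameter recovery from simulated data (every parameter within 3 SE at
n = 20,000) and by rank-correlation > 0.95 between retrained and original
PhenoAge on cohorts whose mortality is driven by the original predictor.

## CPRS and risk groups

`CPRS_i = Σ_k h_k·PRS_ik` with per-sex incidence weights `h_k`. Site PRSs
are z-standardized within sex before weighting (population SD); raw sums
across sites would be scale-incoherent since each PRS has an arbitrary
variance. Standardization can be disabled for pre-harmonized inputs. The
shipped weight table holds *approximate* UK age-standardized incidences per
100,000 for 20 sites by sex and is an editable input, not a constant —
sex-specific sites carry zero weight in the other sex.

Risk groups cut a score at quantiles — quintile (20/60/20,
low/intermediate/high), quartile, or tertile for sensitivity analyses —
within sex, using type-7 quantiles with boundary values assigned to the
lower stratum (deterministic under ties; ties heavy enough to empty a
stratum raise with the cut points). The same machinery groups PhenoAgeAccel.

## Survival analysis

Follow-up runs from baseline to the first of diagnosis, death, loss, or
administrative censoring; death, loss and administrative end all censor the
cancer outcome (no competing-risk modelling). Cox models use lifelines'
partial likelihood with Efron tie handling (ties are rare with continuous
simulated times). Chronological age at baseline is an adjustment covariate,
not the time scale. Model 1 adjusts for age, height, family history of
cancer, Townsend deprivation index and 10 ancestry PCs; Model 2 adds the
CPRS and lifestyle index. Proportionality is screened per term by the
scaled-Schoenfeld correlation-with-time (rank) test at α = 0.05 and
*reported*, never auto-acted upon. The p-for-trend over ordered exposure
groups is the Wald p of the single 0/1/2 ordinal code refitted in place of
the group dummies (asymptotically equivalent to the score test; lifelines
exposes no per-term score test). Fits with fewer than 10 events per
parameter warn rather than fail.

An independent textbook Newton–Raphson partial-likelihood solver lives in
the test suite and must agree with the production path to 1e-6 on a 50-row
fixture — the production fit is never its own oracle.

Missing covariates are filled by single median/mode imputation with an audit
table. This is a documented simplification of multiple imputation by chained
equations: point estimates are essentially unaffected under MCAR missingness
of the rates simulated here, but between-imputation variance is not
propagated, so imputed-data SEs are slightly anticonservative. Sensitivity
filters (exclude events in the first two years, complete-case, unrelated-
subset flag) reproduce the standard robustness checks; kinship inference is
out of scope and the unrelated subset is a flag column.

## Absolute risk, interaction, screening curves

Incidence rates are cases/person-years × 100,000 with a normal-approximation
CI (rate ± 1.96·rate/√cases); an exact Poisson (chi-square) interval is
available by flag. Five-year absolute risk is 5 × rate × 100; the
age-standardized variant weights 5-year age bands by the whole-cohort age
distribution (the "standard" population is the pooled analysis cohort —
external standards can be passed in). Risk differences get percentile
bootstrap CIs resampling participants with replacement, stratified by sex;
BCa was not used because the percentile interval is the simplest method
consistent with seeded reproducibility and the estimand is a smooth
difference of rates.

RERI = HR11 − HR10 − HR01 + 1 and AP = RERI/HR11 are computed from a joint
2×2 Cox model; three-level genetic risk is collapsed to its high-vs-low
margin (intermediate rows dropped) so the interaction is a clean double
dichotomy. Percentile bootstrap CIs refit the joint model per resample;
resamples that empty a cell are redrawn and counted, and more than 10%
redraws abort (the cells are too sparse for the bootstrap to mean anything).

Screening curves compute the 5-year absolute risk in a ±2.5-year sliding
window on a 1-year age grid (smoothing by window overlap only), and the
threshold crossing (default 2%) is linearly interpolated between bracketing
grid ages; a curve that never reaches the threshold is flagged rather than
extrapolated.

## The synthetic cohort generator

The generator emulates the structure of a middle-aged population cohort so
that every analysis step can be validated by parameter recovery. Defaults,
chosen once from the emulated study's baseline tables and held fixed:

- ages uniform on 40–70; 46.3% male; ~7.1-year administrative censoring.
- nine biomarkers from a multivariate normal on the working scale (CRP
  log-normal), with per-biomarker intercept + slope-in-age means calibrated
  to baseline medians (albumin ≈ 45 g/L falling with age, CRP median
  ≈ 0.15 mg/dL rising, RDW ≈ 13.3%, …), male shifts for creatinine/albumin/
  ALP, modest inflammation-cluster correlations (CRP–WBC 0.3, CRP–albumin
  −0.2, …), and physiologic floors.
- five lifestyle factors as Bernoullis at baseline-table prevalences
  (no current smoking 0.56, no alcohol 0.045, activity 0.64, normal BMI
  0.75, healthy diet 0.25); a latent shift spreads each healthy factor's
  effect over the inflammation markers so that PhenoAgeAccel moves by
  `lifestyle_effect_on_accel` (default −1 year/factor) — reproducing the
  negative lifestyle–aging association as a *generated* property.
- 20 site-PRS columns as independent standard normals; single overall-cancer
  event process (site-specific outcome processes are out of scope).
- cancer times by exact inverse-transform sampling of the Gompertz-PH
  survival function, baseline (b = 0.006/yr, g = 0.08/yr) giving ~5–6%
  incidence over follow-up, log hazard 0.085·(age − mean) +
  ln(1.15)·(PhenoAgeAccel/5) + ln(1.30)·CPRS(z); death times from a separate
  Gompertz (0.004/yr, 0.09/yr) log-linear in the mortality predictor xb, so
  the biomarkers that age a participant also kill them (this is what makes
  clock retraining recover the original ranking).
- missingness injected MCAR per covariate cell; outcome columns protected.

What it does **not** emulate: genotype LD structure, informative or
loss-to-follow-up censoring, assessment-center effects, sampling weights,
correlated site-PRSs, or 20 distinct site-specific outcome processes.
Passing recovery tests therefore demonstrate the *estimators* are correct
under the stated model, not that real-data effect sizes will match; the
headline hazard ratios of the motivating analyses come from a cohort of
~374k participants and are not reproducible at simulation scale.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams
(generator, absolute-risk bootstrap, interaction bootstrap); identical
configs give byte-identical outputs, and every pipeline run records a
config hash. The acceptance script uses a 40,000-participant cohort with
200 risk-difference and 100 interaction bootstrap replicates; the test
suite uses 50,000 participants for hazard-ratio recovery, 50 seeds × 1,500
participants for null-coverage checks, and 20,000 for retraining recovery —
sizes at which 3-SE recovery bands and ≥90% CI coverage are sharp but the
whole suite stays desk-scale.

## Known limitations

- Additive-interaction indices are defined for risk ratios; applying them to
  a continuous outcome (e.g. genetic × lifestyle on PhenoAgeAccel itself) is
  methodologically unsettled and deliberately not implemented.
- The trend test is Wald-based, not a score test (equivalent asymptotically).
- Single imputation understates imputation uncertainty (see above).
- The shipped CPRS weight table is approximate and illustrative; analyses of
  real cohorts must supply their own incidence weights and PRS inputs.
- Rate CIs use a normal approximation that degrades below ~20 cases; the
  exact Poisson interval is available by flag.
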