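# Methods

## The identification problem and the RPC model

Age-period-cohort (APC) regressions decompose an outcome trend into
effects of chronological age, calendar period and birth cohort. Because
`age = period − cohort` holds exactly for single-measure variables, the
three-way linear design is rank deficient and the effects are jointly
unidentified; every classical remedy (dropped or equated levels,
intrinsic estimators, proxy characteristics) buys identification with a
constraint that may be wrong.

The risk-period-cohort (RPC) approach replaces chronological age with
an *age-related risk index*: the fitted value of an internal regression
of a baseline outcome on age and other risk factors,

    Y0_i  = mu + beta·age_i + alpha'·x_i + eps_i
    risk_i = mu^ + beta^·age_i + alpha^'·x_i .

Because the index mixes age with independently varying risk factors, it
is not a linear function of period and cohort, and the outcome model

    Y_i = mu* + beta*·risk_i + Gamma*·cohort_i + Lambda*·period_i + e_i

is identified — *provided* the index is not nearly collinear with age.
Three assumptions carry the method: (1) risk is not linearly dependent
on age; (2) the needed variables are in the data; (3) the risk model is
correctly specified. Assumption 1 is checkable: the package reports the
age-risk Pearson correlation (admissible at ≤ 0.85, compared at printed
two-decimal precision) and the *proportionate chronological age effect*
`beta^/(beta^ + Σ alpha^)`, computed with signed estimates — signed
because small negative covariate slopes can push the ratio above 1, and
that is informative, not an error. When the denominator is within
machine tolerance of zero the ratio is reported as undefined.

A second index variant — *predicted chronological age* — regresses age
itself on the other risk factors and uses the fitted ages. It lives on
the age scale (interpretable units) and is the variant used in the
survey-style pipeline.

The hierarchical variant follows the cross-classified HAPC layout: a
level-1 model with a fixed risk slope and a cell intercept, and a
level-2 decomposition of that intercept into crossed random effects for
period and cohort, estimated by REML. The risk slope is a single fixed
effect: nothing in the model family as used here requires a random
slope, and the cross-classified diagram has none; a random-slope
extension is out of scope.

## Synthetic-data generators

The generators *are* the study conditions; their defaults are not
tuning knobs.

**Validation designs.** Age ~ truncated normal(55, 25) on [30, 80],
rounded to integer years (rounding is part of the variable's
definition, applied before standardization); SEP ~ N(0,1); activity ~
Poisson(1); period (design 2) ~ truncated normal(1980, 30) on
[1950, 2010]; cohort = period − age exactly on the raw scale; residual
noise N(0,1) in both designs (the second design reuses the same noise
law). The outcome is built from the *in-sample standardized* (mean-0,
sd-1, population denominator) covariates so the injected slopes are
standardized coefficients; grids enumerate each slope over
{0, 0.2, 0.4, 0.6, 0.8, 1.0}. The intercept is 0 without loss of
generality. Truncated normals are drawn by inverse CDF so a dataset is
a pure function of its seed; the per-dataset draw order (age, SEP,
activity, [period,] noise[, baseline noise]) is fixed and recorded in
the metadata. Design 2 also emits a `baseline_outcome` — the same
linear predictor without the cohort term and with an independent noise
draw — which is what the internal risk model is fitted on: risk is
meant to be pre-cohort information. (Refitting on the cohort-bearing
outcome itself is exposed as `risk_on="current"` but is not the
reference convention: it provably transfers the whole cohort effect
from Gamma* into Lambda*.)

**Survey-style fixture.** Six two-year waves (2006–2016), integer ages
18–80 (truncated normal 47/20), cohort = period − age. Covariates (sex,
comorbidity count 0–11 via an age-loaded Poisson, 4-level race, family
income-to-poverty ratio on [0,5], binary social support) jointly
predict age with R² ≈ 0.24 (age-risk correlation ≈ 0.49), placing the
predicted-age index comfortably inside the admissible range. The score
is a clipped, rounded exponentiated Gaussian on the log(score+1) scale
— median 2, ~78% of subjects ≤ 4, ~8% at 10+ — with a linear birth-
cohort trend (default 0.007 per birth year) and additive wave effects
(defaults 0, 0.109, 0.095, 0.029, 0.053, 0.053) injected on that scale
and recorded in the metadata. What the fixture does *not* emulate:
survey weights, item-level responses, missingness (no listwise-deletion
machinery is needed), and any real demographic covariance beyond the
age loadings — so passing tests demonstrate recovery of known injected
structure, not agreement with any real survey's estimates.

## Monte Carlo experiments

Both studies run each slope pattern for `reps` replications of
n = 10 000 and summarize per pattern.

**Study 1** reports the mean age-risk correlation and mean
proportionate age effect. Expected values obey closed forms (used as
test oracles): corr → β/√(β²+α₁²+α₂²), proportionate effect →
β/(β+α₁+α₂). A pattern is flagged when the mean correlation, rounded
half-up to two decimals, reaches 0.85 — the round-then-compare
convention is forced by the boundary patterns whose analytic
correlation is 1/√1.40 = 0.8452, which belongs to the 0.85 class
at two-decimal reporting precision. Exactly
29 of the 216 patterns flag; 24 of them have proportionate effect
above 0.60 and the other five sit at 0.56–0.57.

**Study 2** reports the *cohort-effect difference* |mean(Γ − Γ*)| and
the *period effect* |mean(Λ*)|; a pattern fails recovery when either
exceeds the trivial effect size 0.01. The absolute value sits outside
the mean deliberately: per-replication estimates carry OLS sampling
noise whose expected magnitude (≈ 0.01–0.08 depending on the pattern's
collinearity) exceeds the threshold for every pattern, so a
mean-of-absolute criterion would flag the entire grid and say nothing
about the method; the magnitude of the mean isolates systematic bias,
which is the recovery question. Under this criterion exactly the 30
pure-age patterns (β > 0, α₁ = α₂ = 0, any Γ) fail: their risk index is
an affine function of age up to noise slopes, the design is nearly
singular, and the minimum-norm fit splits the age signal between cohort
and period. The resulting bias is ≈ β·σ_cohort/σ_age ≈ 1.53 β, and the
spurious period effect is σ_period/σ_cohort ≈ 0.76 of it — both
signatures visible in every reported pathological row. The bias grows
with β, and recovery holds for every pattern with any non-age signal.

**Antithetic pairing.** Replications are drawn in pairs that share the
covariate draws and negate the residual noise. All reported means are
unbiased; error components linear in the noise cancel exactly within a
pair, which cuts the MC standard error of the mean errors by one to two
orders of magnitude and makes the flag decisions stable at the default
replication counts (100/pattern for study 2, 1000–2000 for study 1).
The pathological bias is invariant under the sign flip and fully
retained. Independent replications are available via
`antithetic=False`.

**Dispersion reporting.** `empirical_se_*` is the Monte Carlo standard
error of the reported mean (SD across replications / √reps). One
pattern deserves a warning label: for the all-null pattern (0,0,0) the
per-replication proportionate effect is a ratio of three iid mean-zero
noise slopes, which is distributed as 1/3 + 0.47·Cauchy — it has no
mean or variance, its sample SD diverges with the replication count,
and any single run's dispersion estimate is itself heavy-tailed (order
0.05–0.5). The package computes the diagnostics for this pattern
rather than erroring, but no stable dispersion number exists for it;
treat its proportionate effect as undefined in practice (it violates
assumption 1 anyway).

**Seeds.** Per-(pattern, pair) seeds are
`SeedSequence([base_seed, pattern_index, pair_index])`, so grid subsets
rerun independently and bitwise-identically.

**Problem sizes.** The package defaults follow the reference design
(n = 10 000; 1000 replications). The shipped acceptance script runs
study 1 at 2000 replications/pattern, study 2 at 100, deep spot checks
of pathological patterns at 20 000, chosen so the flag decisions are
inside their stability regions (see the SE analysis above) while a full
recomputation stays under ~10 minutes on one CPU.

## Numerical choices

* All fixed-effects fits use SVD least squares (`lstsq`): minimum-norm
  on rank-deficient designs, with a `rank_deficient` flag rather than
  silent column dropping — the pathological study-2 fits exist because
  the fits were produced, not refused. The categorical APC fit is the
  one place singularity is an *error*, because there it is the
  identification problem itself and the user must break it with
  `drop_levels`.
* Standard errors from the pseudo-inverse Gram matrix with the
  classical σ² estimate; p-values from the t distribution. Equivalence
  with an independent OLS implementation is tested to 10 significant
  digits on small instances.
* Standardization is always in-sample with the population (ddof = 0)
  denominator; z-scored columns have exactly zero mean, so centered
  no-intercept solves agree with intercept fits to machine precision
  (exploited by the experiment kernels, and tested).
* Threshold comparisons at printed precision use decimal half-up
  rounding on the shortest decimal representation (so 0.845 → 0.85).
* Cohort bins are right-closed width-w year groups anchored so bins end
  on multiples of w (1946–1950, 1951–1955, …); width 1 degenerates to
  per-year labels. Reference levels for categorical fits are the first
  period and earliest cohort bin.
* REML variance components via crossed variance-component formulas; a
  single-level classification gets its component fixed at 0 with a
  warning instead of a degenerate fit.

## Known limitations

* Continuous outcomes only; binary/count/survival risk models are
  extension points, not implemented.
* OLS risk models only; the risk-index interface admits other engines
  but none ship.
* The recovery experiment's conclusions are conditional on a correctly
  specified risk model (assumption 3); misspecification is not
  simulated.
* The survey-style pipeline demonstrates qualitative signatures
  (cohort-trend detection, APC variance inflation); it does not — and
  cannot — reproduce numbers from any real survey.
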