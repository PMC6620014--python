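# riskpc — risk-period-cohort modelling

Age-period-cohort (APC) models decompose an outcome trend into effects
of growing older (age), of the times (period) and of being born into a
particular generation (cohort). They are unidentified: because
`age = period − cohort` exactly, the three-way design is singular and
every classical fix imposes a constraint that may be wrong.

`riskpc` implements the **risk-period-cohort (RPC)** alternative for
epidemiologists and social scientists working with repeated
cross-sections or panels: replace chronological age with an
**age-related risk index** — the fitted value of an internal regression
of a baseline outcome (or of age itself, the *predicted-age* variant)
on age plus other risk factors:

```
Y⁰ᵢ   = μ + β·ageᵢ + αᵀxᵢ + εᵢ             (internal risk model)
riskᵢ = μ̂ + β̂·ageᵢ + α̂ᵀxᵢ                  (age-related risk index)
Yᵢ    = μ* + β*·riskᵢ + Γ*·cohortᵢ + Λ*·periodᵢ + eᵢ   (RPC regression)
```

Because the index mixes age with independently varying risk factors it
is not collinear with period and cohort, and all three dimensions are
estimable — as long as the index is not essentially a rescaled age.
The package ships the admissibility diagnostics (age-risk correlation
against the 0.85 threshold; the proportionate chronological age effect
β̂/(β̂+Σα̂)), fixed-effects and cross-classified mixed (REML) fits,
traditional APC baselines for comparison, the synthetic-data
generators, and the two Monte Carlo experiments that map out exactly
when the approach works and how it fails.

## Worked example

Simulate a cross-section with standardized effects β=0.4 (age),
α₁=0.4 (socioeconomic position), α₂=0.2 (activity) and a true cohort
effect Γ=0.4 with no period effect; build the risk index from the
baseline outcome; check admissibility; fit the RPC regression:

```python
from riskpc import (SimCondition, simulate_study2, fit_risk_model,
                    compute_risk_index, diagnose, fit_rpc_ols)

cond = SimCondition(beta=0.4, alpha1=0.4, alpha2=0.2, gamma=0.4,
                    n=10_000, seed=1)
panel = simulate_study2(cond)

rm = fit_risk_model(panel, ["sep", "activity"], outcome="baseline_outcome")
risk = compute_risk_index(rm, panel)
diag = diagnose(rm, risk, panel.col("age"))
print(f"age-risk correlation {diag.age_risk_correlation:.3f} "
      f"(admissible: {diag.admissible})")
print(f"proportionate age effect {diag.proportionate_age_effect:.3f}")

fit = fit_rpc_ols(panel, risk)
print(f"cohort slope {fit.cohort_slope_star:.3f} "
      f"+- {fit.standard_errors['cohort']:.3f} (truth 0.4)")
print(f"period slope {fit.period_slope_star:.3f} "
      f"+- {fit.standard_errors['period']:.3f} (truth 0)")
```

Output:

```
age-risk correlation 0.676 (admissible: True)
proportionate age effect 0.405
cohort slope 0.352 +- 0.021 (truth 0.4)
period slope 0.034 +- 0.019 (truth 0)
```

The index correlates with age at 0.68 — well under the 0.85 bound, so
the RPC design is well conditioned — and the single-replication fit
recovers the cohort effect and the null period effect within sampling
error; averaged over replications the recovery error is below the
trivial effect size 0.01 (that is what the study-2 experiment
verifies). Had we set α₁=α₂=0 the correlation would be 1.00, the
design singular, and the fit would come back `rank_deficient` with the
age signal leaking into the cohort and period slopes — the pathological
regime the diagnostics are there to catch.

The end-to-end survey-style demonstration (`rpc demo --out-dir out/`)
generates a skewed 0–27 screening score over six two-year waves with a
known injected cohort trend, builds a predicted-age risk index
(age-risk correlation ≈ 0.49), and prints a side-by-side RPC vs APC
coefficient table: the RPC fit detects the injected cohort trend (rank
correlation with cohort order > 0.9) while the traditional APC fit
shows the same point-estimate direction with roughly twice the
standard errors.

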