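"""Synthetic data generators for the RPC methodology and its validation.

Three generators are provided:

* :func:`simulate_study1` — cross-sectional baseline-health data whose
  outcome is a linear function of standardized chronological age,
  socioeconomic position (SEP) and a Poisson physical-activity count,
  plus unit Gaussian noise.  Used to study how the age slope drives the
  correlation between chronological age and a fitted risk index.
* :func:`simulate_study2` — the same cross-section augmented with a
  calendar period drawn from a truncated normal and a birth cohort
  defined exactly as ``period - age``, with an additional standardized
  cohort effect on the outcome and no period effect.  Used to study
  recovery of cohort/period effects by the RPC regression.
* :func:`simulate_nhanes_like` — a survey-style panel emulating six
  two-year waves of a depression-screening instrument: a right-skewed
  bounded integer score (0-27), demographic covariates that jointly
  predict age with moderate accuracy, and known cohort/period effects
  injected on the log(score+1) scale.

All truncated-normal draws use inverse-CDF sampling so that the number
of RNG variates per dataset is fixed, making every dataset a pure
function of its seed.  The per-dataset draw order is documented in each
generator and recorded in the dataset metadata.

Each generator accepts ``noise_sign``; ``-1`` yields the antithetic twin
of the same seed (identical covariate draws, negated residual noise),
which the Monte Carlo drivers use for variance reduction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .data import PanelDataset, SimCondition, standardize

GENERATOR_VERSION = "riskpc-0.1.0"

# Generative settings of the two validation designs: chronological age is
# a rounded truncated normal on [30, 80] (mean 55, sd 25); calendar
# period a truncated normal on [1950, 2010] (mean 1980, sd 30); SEP is
# standard normal; activity is Poisson(1); residual noise standard
# normal; the intercept is 0 without loss of generality.
AGE_TRUNC = (55.0, 25.0, 30.0, 80.0)
PERIOD_TRUNC = (1980.0, 30.0, 1950.0, 2010.0)


def truncated_normal(rng: np.random.Generator, n: int,
                     mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF truncated-normal sampler (exactly ``n`` uniforms)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.random(n)
    return mean + sd * ndtri(a + u * (b - a))


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Analytic mean of the truncated normal (used as a test oracle)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
    z = ndtr(b) - ndtr(a)
    return mean + sd * (phi(a) - phi(b)) / z


def _draw_base_covariates(rng: np.random.Generator, n: int):
    """Draws shared by both validation designs, in documented order:
    age uniforms, SEP normals, activity Poissons."""
    age = np.round(truncated_normal(rng, n, *AGE_TRUNC))
    sep = rng.standard_normal(n)
    activity = rng.poisson(1.0, n).astype(float)
    return age, sep, activity


def simulate_study1(cond: SimCondition, noise_sign: int = 1,
                    strict_grid: bool = False) -> PanelDataset:
    """Generate one cross-sectional baseline-health replication.

    Draw order: age uniforms, SEP, activity, noise.  The outcome is
    built from the in-sample standardized covariates so the injected
    slopes are on the standardized-coefficient scale; the raw covariate
    columns are what the table stores.
    """
    cond.validate(strict_grid=strict_grid)
    if cond.gamma is not None:
        raise ValueError("study-1 conditions do not carry a cohort slope; "
                         "use simulate_study2 for gamma != None")
    rng = np.random.default_rng(cond.seed)
    age, sep, activity = _draw_base_covariates(rng, cond.n)
    eps = rng.standard_normal(cond.n)
    outcome = (cond.beta * standardize(age)
               + cond.alpha1 * standardize(sep)
               + cond.alpha2 * standardize(activity)
               + noise_sign * eps)
    import pandas as pd
    table = pd.DataFrame({"outcome": outcome, "age": age,
                          "sep": sep, "activity": activity})
    meta = {"condition": cond.asdict(), "design": "study1",
            "generator": GENERATOR_VERSION, "noise_sign": int(noise_sign),
            "draw_order": ["age", "sep", "activity", "noise"]}
    return PanelDataset(table, meta)


def simulate_study2(cond: SimCondition, noise_sign: int = 1,
                    strict_grid: bool = False) -> PanelDataset:
    """Generate one replication with cohort structure.

    Draw order: age uniforms, SEP, activity, period uniforms, noise,
    baseline noise.  Cohort is ``period - age`` exactly on the raw
    scale; the current-state outcome follows the linear model with a
    standardized cohort effect and no period effect.  A baseline
    outcome — the same linear predictor without the cohort term and
    with an independent noise draw — is included so an internal risk
    model can be fitted on pre-cohort information.
    """
    cond.validate(strict_grid=strict_grid)
    if cond.gamma is None:
        raise ValueError("study-2 conditions require a cohort slope gamma")
    rng = np.random.default_rng(cond.seed)
    age, sep, activity = _draw_base_covariates(rng, cond.n)
    period = truncated_normal(rng, cond.n, *PERIOD_TRUNC)
    eps = rng.standard_normal(cond.n)
    eps0 = rng.standard_normal(cond.n)
    cohort = period - age
    signal = (cond.beta * standardize(age)
              + cond.alpha1 * standardize(sep)
              + cond.alpha2 * standardize(activity))
    outcome = signal + cond.gamma * standardize(cohort) + noise_sign * eps
    baseline = signal + noise_sign * eps0
    import pandas as pd
    table = pd.DataFrame({"outcome": outcome, "baseline_outcome": baseline,
                          "age": age, "sep": sep, "activity": activity,
                          "period": period, "cohort": cohort})
    meta = {"condition": cond.asdict(), "design": "study2",
            "generator": GENERATOR_VERSION, "noise_sign": int(noise_sign),
            "draw_order": ["age", "sep", "activity", "period",
                           "noise", "baseline_noise"]}
    return PanelDataset(table, meta)


# ---------------------------------------------------------------------------
# Survey-style fixture
# ---------------------------------------------------------------------------

#: Default injected period effects on the log(score+1) scale, one per
#: two-year wave 2005-06 ... 2015-16 (first wave is the reference).
DEFAULT_PERIOD_EFFECTS = (0.0, 0.109, 0.095, 0.029, 0.053, 0.053)

#: Default injected linear birth-cohort trend per birth year on the
#: log(score+1) scale.
DEFAULT_COHORT_TREND = 0.007

_NHANES_PERIODS = np.array([2006, 2008, 2010, 2012, 2014, 2016])
_RACE_LEVELS = ("hispanic", "nh_white", "nh_black", "other")
_RACE_PROBS = (0.170, 0.469, 0.210, 0.151)


def simulate_nhanes_like(n: int = 27_496, seed: int = 0,
                         cohort_trend: float = DEFAULT_COHORT_TREND,
                         period_effects=DEFAULT_PERIOD_EFFECTS) -> PanelDataset:
    """Survey-style depression-screening panel with known truth.

    The score is a clipped, rounded exponentiated Gaussian on the
    log(score+1) scale, which produces the strong right skew of a
    0-27 questionnaire total (majority of subjects at 4 or below).
    Covariates (sex, comorbidity count 0-11, 4-level race, family
    income-to-poverty ratio 0-5, binary social support) are generated so
    that together they predict chronological age with a moderate
    coefficient of determination (about 0.24), keeping the predicted-age
    risk index well inside the collinearity-admissible range.  The
    injected cohort trend and additive period effects act on the
    log(score+1) scale and are recorded in the metadata so recovery can
    be tested.

    Draw order: period, age uniforms, comorbidity Poissons, income,
    support uniforms, sex uniforms, race, score noise.
    """
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    period_effects = np.asarray(period_effects, dtype=float)
    if period_effects.shape != (6,):
        raise ValueError("period_effects must have length 6 "
                         f"(one per wave), got {period_effects.shape}")
    rng = np.random.default_rng(seed)
    period = _NHANES_PERIODS[rng.integers(0, 6, n)]
    age = np.round(truncated_normal(rng, n, 47.0, 20.0, 18.0, 80.0))
    cohort = period - age
    z = (age - age.mean()) / age.std()
    comorbidities = np.minimum(rng.poisson(np.exp(-1.0 + 0.8 * z)), 11)
    income_ratio = np.clip(rng.normal(2.4 + 0.25 * z, 1.5), 0.0, 5.0)
    social_support = (rng.random(n) < expit(0.3 + 0.2 * z)).astype(int)
    sex = (rng.random(n) < 0.515).astype(int)
    race = rng.choice(len(_RACE_LEVELS), n, p=_RACE_PROBS)

    wave = (period - _NHANES_PERIODS[0]) // 2
    log_mean = (1.00
                + cohort_trend * (cohort - cohort.mean())
                + period_effects[wave]
                + 0.10 * comorbidities
                - 0.18 * social_support
                - 0.03 * income_ratio)
    latent = log_mean + rng.normal(0.0, 1.0, n)
    score = np.clip(np.round(np.exp(latent) - 1.0), 0, 27).astype(int)

    import pandas as pd
    table = pd.DataFrame({
        "score": score, "age": age, "period": period, "cohort": cohort,
        "sex": sex, "comorbidities": comorbidities,
        "race": pd.Categorical.from_codes(race, list(_RACE_LEVELS)),
        "income_ratio": income_ratio, "social_support": social_support,
    })
    meta = {"design": "nhanes_like", "generator": GENERATOR_VERSION,
            "n": int(n), "seed": int(seed),
            "cohort_trend": float(cohort_trend),
            "period_effects": period_effects.tolist(),
            "score_intercept": 1.00, "score_noise_sd": 1.0,
            "score_loadings": {"comorbidities": 0.10,
                               "social_support": -0.18,
                               "income_ratio": -0.03},
            "draw_order": ["period", "age", "comorbidities", "income_ratio",
                           "social_support", "sex", "race", "score_noise"]}
    return PanelDataset(table, meta)
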