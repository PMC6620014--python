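"""Internal risk models and collinearity diagnostics.

The central object of the RPC approach is the *age-related risk index*:
the fitted value of an internal regression of a baseline outcome on
chronological age and other risk factors,

    risk_i = mu_hat + beta_hat * age_i + alpha_hat' x_i.

Substituting this multidimensional index for chronological age in a
period/cohort regression breaks the exact linear dependency
``age = period - cohort`` — provided the index is not itself (nearly)
collinear with age.  Two diagnostics quantify that requirement:

* the Pearson correlation between age and the index, which should stay
  at or below a threshold (0.85 by convention) for the subsequent
  regression to be well conditioned;
* the *proportionate chronological age effect*
  ``beta_hat / (beta_hat + sum(alpha_hat))``, the share of the fitted
  risk equation attributable to the age slope.  Signed estimates are
  used, so the ratio can exceed 1 when small negative covariate slopes
  enter the denominator.

A second flavour of index — *predicted chronological age* — regresses
age itself on the other risk factors and uses the fitted ages; it lives
on the age scale and is the variant used in the survey-style pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import dependent_columns, ols
from .data import PanelDataset

DEFAULT_CORR_THRESHOLD = 0.85


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, matching printed-table precision.

    Operates on the shortest decimal representation of ``x`` so that,
    e.g., 0.845 rounds to 0.85 even though its binary value is
    fractionally below the tie.
    """
    import decimal
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class RiskModelFit:
    """Fitted internal risk model (ordinary least squares)."""

    intercept_hat: float
    age_slope_hat: float
    cov_slopes_hat: pd.Series
    residual_variance: float
    r_squared: float
    design_spec: list[str]
    standardized: bool
    age_col: str = "age"
    outcome_col: str = "outcome"
    centers: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    scales: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def slope_sum(self) -> float:
        return float(self.age_slope_hat + self.cov_slopes_hat.sum())


@dataclass
class RiskDiagnostics:
    """Admissibility diagnostics for an age-related risk index."""

    age_risk_correlation: float
    collinearity_margin: float
    proportionate_age_effect: float | None
    threshold: float
    admissible: bool


def _design_matrix(data: PanelDataset, columns: list[str]) -> np.ndarray:
    cols = []
    for name in columns:
        if name not in data.table.columns:
            raise KeyError(f"panel has no column {name!r}")
        col = data.table[name]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(f"column {name!r} is not numeric; encode it first")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _expand_categoricals(table: pd.DataFrame, columns) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-encode non-numeric covariates (first level as reference)."""
    frames, names = [], []
    for name in columns:
        if name not in table.columns:
            raise KeyError(f"panel has no column {name!r}")
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            frames.append(col.astype(float))
            names.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            frames.append(dummies)
            names.extend(dummies.columns)
    return pd.concat(frames, axis=1), names


def fit_risk_model(data: PanelDataset, covariates, standardize: bool = True,
                   outcome: str = "outcome", age_col: str = "age") -> RiskModelFit:
    """OLS fit of the internal risk model: outcome on age plus covariates.

    With ``standardize`` (the convention of the simulation designs) the
    age and covariate columns are z-scored in-sample before fitting, so
    the slopes are on the standardized-coefficient scale; the
    standardization constants are stored on the fit so the index can be
    reproduced on the training data or applied to new data on the same
    scale.
    """
    covariates = list(covariates)
    y = data.col(outcome).astype(float)
    columns = [age_col] + covariates
    raw = _design_matrix(data, columns)
    n, p = raw.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} rows to fit {p} slopes, got {n}")

    centers = raw.mean(axis=0)
    scales = raw.std(axis=0)
    if standardize:
        if (scales == 0).any():
            const = [c for c, s in zip(columns, scales) if s == 0]
            raise ValueError(f"cannot standardize constant column(s) {const}")
        design = (raw - centers) / scales
    else:
        design = raw
        centers = np.zeros(p)
        scales = np.ones(p)

    X = np.column_stack([np.ones(n), design])
    names = ["Intercept"] + columns
    res = ols(X, y, names)
    if res.rank_deficient:
        dep = dependent_columns(X, names)
        raise ValueError(
            "risk-model design is rank deficient; linearly dependent "
            f"column(s): {dep}"
        )
    return RiskModelFit(
        intercept_hat=float(res.params["Intercept"]),
        age_slope_hat=float(res.params[age_col]),
        cov_slopes_hat=res.params[covariates],
        residual_variance=res.residual_variance,
        r_squared=res.r_squared,
        design_spec=columns,
        standardized=standardize,
        age_col=age_col,
        outcome_col=outcome,
        centers=pd.Series(centers, index=columns),
        scales=pd.Series(scales, index=columns),
    )


def compute_risk_index(fit: RiskModelFit, data: PanelDataset) -> np.ndarray:
    """Fitted values of the risk model: the age-related risk index."""
    raw = _design_matrix(data, fit.design_spec)
    design = (raw - fit.centers.to_numpy()) / fit.scales.to_numpy()
    coef = np.concatenate(([fit.age_slope_hat], fit.cov_slopes_hat.to_numpy()))
    return fit.intercept_hat + design @ coef


def predicted_age_index(data: PanelDataset, covariates, age_col: str = "age",
                        return_fit: bool = False):
    """Predicted chronological age from the other risk factors.

    OLS of age on the covariates (non-numeric covariates are
    dummy-encoded); the fitted ages, on the age scale, are the index.
    """
    covariates = list(covariates)
    if age_col in covariates:
        raise ValueError("covariates must exclude the age column")
    age = data.col(age_col).astype(float)
    design, names = _expand_categoricals(data.table, covariates)
    X = np.column_stack([np.ones(len(age)), design.to_numpy(dtype=float)])
    res = ols(X, age, ["Intercept"] + names)
    if res.rank_deficient:
        dep = dependent_columns(X, ["Intercept"] + names)
        raise ValueError(
            f"predicted-age design is rank deficient; dependent column(s): {dep}"
        )
    index = X @ res.params.to_numpy()
    return (index, res) if return_fit else index


def age_risk_correlation(risk: np.ndarray, age: np.ndarray,
                         threshold: float = DEFAULT_CORR_THRESHOLD,
                         rounding_decimals: int = 2) -> RiskDiagnostics:
    """Correlation-only diagnostics (for indices without an age slope,
    such as predicted chronological age)."""
    risk = np.asarray(risk, dtype=float)
    age = np.asarray(age, dtype=float)
    if risk.shape != age.shape or risk.size < 3:
        raise ValueError("risk and age must be equal-length vectors (n >= 3)")
    if age.std() == 0 or risk.std() == 0:
        raise ValueError("correlation undefined: constant age or constant risk")
    corr = float(np.corrcoef(age, risk)[0, 1])
    rounded = round_half_up(abs(corr), rounding_decimals)
    return RiskDiagnostics(
        age_risk_correlation=corr,
        collinearity_margin=1.0 - abs(corr),
        proportionate_age_effect=None,
        threshold=threshold,
        admissible=rounded <= threshold,
    )


def proportionate_age_effect(fit: RiskModelFit) -> float | None:
    """beta_hat / (beta_hat + sum alpha_hat), with signed estimates.

    Returns ``None`` when the denominator is within machine tolerance of
    zero (the ratio is then meaningless, not merely large).
    """
    denom = fit.slope_sum()
    scale = max(1.0, abs(fit.age_slope_hat) + float(fit.cov_slopes_hat.abs().sum()))
    if abs(denom) < 1e-12 * scale:
        return None
    return float(fit.age_slope_hat / denom)


def diagnose(fit: RiskModelFit, risk: np.ndarray, age: np.ndarray,
             threshold: float = DEFAULT_CORR_THRESHOLD,
             rounding_decimals: int = 2) -> RiskDiagnostics:
    """Full admissibility diagnostics for a fitted risk model.

    The admissibility comparison uses the correlation rounded to
    ``rounding_decimals`` (printed-table precision): an index is
    admissible when the rounded absolute correlation does not exceed the
    threshold.
    """
    diag = age_risk_correlation(risk, age, threshold, rounding_decimals)
    diag.proportionate_age_effect = proportionate_age_effect(fit)
    return diag
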