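"""RPC outcome regressions and traditional APC baselines.

The RPC regression replaces chronological age with the age-related risk
index in an otherwise standard age-period-cohort decomposition:

    Y_i = mu* + beta* risk_i + Gamma* cohort_i + Lambda* period_i + e_i

Because the risk index is a multidimensional combination of age and
other risk factors, the design is (generically) full rank even though
``age = period - cohort`` exactly.  In the pathological case where the
index is essentially a rescaled age, the design approaches singularity;
fits are then still produced — via a minimum-norm least-squares solver
— and flagged, so the resulting instability is observable rather than
hidden.

Traditional APC baselines are provided for comparison: the numeric
variant (outcome on age, covariates and cohort), and the categorical
variant in which period and binned cohort enter as dummies and the user
must drop levels to break the exact dependency — the identification
problem surfaces as an explicit singularity error if they do not.

A hierarchical variant follows the cross-classified HAPC layout: a
within-subject model with a fixed risk slope, and crossed random
intercepts for period and cohort estimated by REML.  The classification
is crossed, not nested: each period contains many cohorts and each
cohort appears in several periods, but not all combinations occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import OLSResult, ols
from .data import PanelDataset, standardize


@dataclass
class RPCFit:
    """Fixed-effects fit of an RPC or APC regression.

    ``params``/``standard_errors``/``p_values`` are aligned named
    vectors covering every coefficient; categorical terms are named
    ``cohort[<level>]`` / ``period[<level>]`` with the reference level
    absorbed into the intercept.
    """

    params: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    adjusted_r_squared: float
    rank_deficient: bool
    df_resid: int
    reference_levels: dict = field(default_factory=dict)

    def _group(self, prefix: str):
        mask = self.params.index.str.startswith(prefix + "[")
        if mask.any():
            out = self.params[mask].copy()
            out.index = [i[len(prefix) + 1:-1] for i in out.index]
            return out
        if prefix in self.params.index:
            return float(self.params[prefix])
        return None

    @property
    def intercept_star(self) -> float:
        return float(self.params["Intercept"])

    @property
    def risk_slope_star(self):
        return float(self.params["risk"]) if "risk" in self.params.index else None

    @property
    def cohort_slope_star(self):
        return self._group("cohort")

    @property
    def period_slope_star(self):
        return self._group("period")


@dataclass
class HAPCFit:
    """Cross-classified mixed-model fit (REML)."""

    fixed_intercept: float
    fixed_slopes: pd.Series
    period_random_intercepts: pd.Series
    cohort_random_intercepts: pd.Series
    variance_components: dict
    converged: bool


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def log1p_outcome(scores) -> np.ndarray:
    """Natural log of (score + 1), the variance-stabilizing transform
    for right-skewed bounded questionnaire totals."""
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any():
        bad = np.flatnonzero(scores < 0)[:10].tolist()
        raise ValueError(f"scores must be non-negative; offending rows {bad}")
    return np.log1p(scores)


def bin_cohorts(birth_years, width: int = 5, origin: int | None = None) -> pd.Categorical:
    """Group birth years into right-closed bins of ``width`` years.

    Bins are anchored at ``origin`` (the first year of some bin); with
    the default anchor, years 1946-1950 share the label ``1946-1950``
    and 1951 starts the next bin, matching conventional five-year
    cohort tables.  ``width=1`` labels each year by itself.
    """
    years = np.asarray(birth_years)
    if not np.all(np.equal(np.mod(years, 1), 0)):
        raise ValueError("birth years must be integers")
    years = years.astype(int)
    width = int(width)
    if width < 1:
        raise ValueError("width must be >= 1")
    if origin is None:
        # anchor so that bins end on calendar years = 0 (mod width),
        # e.g. 1946-1950 for width 5
        origin = width * (years.min() // width) + 1
        if origin > years.min():
            origin -= width
    k = (years - origin) // width
    starts = origin + k * width
    if width == 1:
        labels = starts.astype(str)
        cats = np.unique(starts).astype(str)
    else:
        labels = np.char.add(np.char.add(starts.astype(str), "-"),
                             (starts + width - 1).astype(str))
        u = np.unique(starts)
        cats = np.char.add(np.char.add(u.astype(str), "-"),
                           (u + width - 1).astype(str))
    return pd.Categorical(labels, categories=list(cats), ordered=True)


def _dummies(values, term: str, reference=None, drop_levels=()) -> tuple[pd.DataFrame, object]:
    """Dummy-encode a categorical term, dropping the reference level and
    any extra levels requested (for breaking APC dependencies)."""
    cat = values if isinstance(values, pd.Categorical) else pd.Categorical(values)
    levels = list(cat.categories)
    if not levels:
        raise ValueError(f"{term} has no levels")
    counts = pd.Series(cat).value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"{term} has empty level(s): {empty}")
    reference = levels[0] if reference is None else reference
    dropped = {reference, *drop_levels}
    keep = [lv for lv in levels if lv not in dropped]
    codes = pd.Series(cat)
    frame = pd.DataFrame(
        {f"{term}[{lv}]": (codes == lv).astype(float).to_numpy() for lv in keep}
    )
    return frame, reference


def _as_rpcfit(res: OLSResult, reference_levels: dict) -> RPCFit:
    return RPCFit(
        params=res.params,
        standard_errors=res.bse,
        p_values=res.pvalues,
        r_squared=res.r_squared,
        adjusted_r_squared=res.adjusted_r_squared,
        rank_deficient=res.rank_deficient,
        df_resid=res.df_resid,
        reference_levels=reference_levels,
    )


# ---------------------------------------------------------------------------
# fixed-effects fits
# ---------------------------------------------------------------------------

def fit_rpc_ols(data: PanelDataset, risk, cohort_as: str = "numeric",
                period_as: str = "numeric", outcome: str = "outcome",
                cohort_col: str = "cohort", period_col: str = "period",
                standardize_numeric: bool = True,
                cohort_ref=None, period_ref=None) -> RPCFit:
    """OLS of the outcome on risk + cohort + period.

    Numeric cohort/period (the simulation-study convention) are
    z-scored in-sample along with the risk index, so the slopes are
    standardized coefficients directly comparable with injected effect
    sizes.  Categorical terms enter as dummies against a stated
    reference level (first period, earliest cohort by default).

    A numerically singular design is *not* an error here: the
    minimum-norm solution is returned with ``rank_deficient`` set, so
    pathological near-collinearity (risk essentially proportional to
    age) remains diagnosable.
    """
    risk = np.asarray(risk, dtype=float)
    y = data.col(outcome).astype(float)
    if risk.shape != y.shape:
        raise ValueError(
            f"risk length {risk.size} does not match table rows {y.size}")

    refs: dict = {}
    parts = [pd.DataFrame({"risk": standardize(risk) if standardize_numeric else risk})]
    for term, how, col, ref in (("cohort", cohort_as, cohort_col, cohort_ref),
                                ("period", period_as, period_col, period_ref)):
        if how == "numeric":
            vals = data.col(col).astype(float)
            parts.append(pd.DataFrame(
                {term: standardize(vals) if standardize_numeric else vals}))
        elif how == "categorical":
            frame, used_ref = _dummies(data.table[col], term, reference=ref)
            refs[term] = used_ref
            parts.append(frame)
        else:
            raise ValueError(f"{term}_as must be 'numeric' or 'categorical'")
    design = pd.concat(parts, axis=1)
    X = np.column_stack([np.ones(len(y)), design.to_numpy(dtype=float)])
    res = ols(X, y, ["Intercept"] + list(design.columns))
    if res.rank_deficient:
        warnings.warn("RPC design is numerically singular; returning the "
                      "minimum-norm solution (rank_deficient=True)", stacklevel=2)
    return _as_rpcfit(res, refs)


def fit_apc_ols(data: PanelDataset, mode: str = "categorical",
                drop_levels: dict | None = None, covariates=(),
                outcome: str = "outcome", age_as: str = "numeric",
                cohort_col: str = "cohort", period_col: str = "period",
                age_col: str = "age", quadratic_age: bool = False,
                standardize_numeric: bool = True,
                cohort_ref=None, period_ref=None) -> RPCFit:
    """Traditional APC regression baselines.

    ``mode='numeric'`` is the linear generating-model check: outcome on
    (standardized) age, covariates and cohort.  ``mode='categorical'``
    is the applied variant: numeric (or categorical) age plus dummy
    period and dummy (typically binned) cohort; ``drop_levels`` maps
    ``'period'``/``'cohort'``/``'age'`` to extra levels removed beyond
    the reference to break the linear dependency.  A specification that
    leaves the design singular raises an explicit error — this is the
    identification problem, not a numerical accident.
    """
    drop_levels = drop_levels or {}
    y = data.col(outcome).astype(float)
    refs: dict = {}
    parts: list[pd.DataFrame] = []

    if mode == "numeric":
        cols = {}
        for name in (age_col, *covariates, cohort_col):
            vals = data.col(name).astype(float)
            cols[name] = standardize(vals) if standardize_numeric else vals
        parts.append(pd.DataFrame(cols))
    elif mode == "categorical":
        if age_as == "numeric":
            age = data.col(age_col).astype(float)
            frame = {"age": age}
            if quadratic_age:
                frame["age_sq"] = age ** 2
            parts.append(pd.DataFrame(frame))
        elif age_as == "categorical":
            frame, ref = _dummies(data.table[age_col].astype(int).astype(str),
                                  "age", drop_levels=drop_levels.get("age", ()))
            refs["age"] = ref
            parts.append(frame)
        else:
            raise ValueError("age_as must be 'numeric' or 'categorical'")
        for name in covariates:
            parts.append(pd.DataFrame({name: data.col(name).astype(float)}))
        for term, col, ref in (("period", period_col, period_ref),
                               ("cohort", cohort_col, cohort_ref)):
            frame, used_ref = _dummies(data.table[col], term, reference=ref,
                                       drop_levels=drop_levels.get(term, ()))
            refs[term] = used_ref
            parts.append(frame)
    else:
        raise ValueError("mode must be 'numeric' or 'categorical'")

    design = pd.concat(parts, axis=1)
    X = np.column_stack([np.ones(len(y)), design.to_numpy(dtype=float)])
    res = ols(X, y, ["Intercept"] + list(design.columns))
    if mode == "categorical" and res.rank_deficient:
        raise np.linalg.LinAlgError(
            "APC design is singular (age = period - cohort): the supplied "
            "drop_levels specification does not break the linear dependency")
    return _as_rpcfit(res, refs)


# ---------------------------------------------------------------------------
# hierarchical (cross-classified) fits
# ---------------------------------------------------------------------------

def _fit_hapc(table: pd.DataFrame, y: np.ndarray, fixed: pd.DataFrame,
              period_labels, cohort_labels) -> HAPCFit:
    import statsmodels.formula.api as smf

    df = fixed.copy()
    df["_y"] = y
    df["_period"] = pd.Categorical(period_labels)
    df["_cohort"] = pd.Categorical(cohort_labels)
    df["_g"] = 1

    vc = {}
    components = {"period": 0.0, "cohort": 0.0}
    for term in ("period", "cohort"):
        nlev = df[f"_{term}"].nunique()
        if nlev < 2:
            warnings.warn(f"{term} has a single level; its variance component "
                          "is fixed at 0", stacklevel=3)
        else:
            vc[term] = f"0 + C(_{term})"
    if not vc:
        raise ValueError("need at least one classification with >= 2 levels")

    fixed_terms = list(fixed.columns)
    formula = "_y ~ " + (" + ".join(fixed_terms) if fixed_terms else "1")
    model = smf.mixedlm(formula, df, groups="_g", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs", maxiter=200)

    for name, value in zip(model.exog_vc.names, result.vcomp):
        components[name] = float(value)
    components["residual"] = float(result.scale)

    re = result.random_effects[1]

    def _extract(term: str) -> pd.Series:
        prefix = f"{term}[C(_{term})["
        items = {k[len(prefix):-2]: float(v) for k, v in re.items()
                 if k.startswith(prefix)}
        levels = [str(lv) for lv in df[f"_{term}"].cat.categories]
        return pd.Series({lv: items.get(lv, 0.0) for lv in levels})

    fe = result.fe_params
    return HAPCFit(
        fixed_intercept=float(fe["Intercept"]),
        fixed_slopes=pd.Series({k: float(v) for k, v in fe.items()
                                if k != "Intercept"}),
        period_random_intercepts=_extract("period"),
        cohort_random_intercepts=_extract("cohort"),
        variance_components=components,
        converged=bool(result.converged),
    )


def fit_rpc_hapc(data: PanelDataset, risk, outcome: str = "outcome",
                 cohort_col: str = "cohort", period_col: str = "period") -> HAPCFit:
    """RPC hierarchical model: fixed risk slope, crossed random
    intercepts for period and cohort (REML).

    The risk slope is a single fixed effect common to all
    period-by-cohort cells; predicted random intercepts (BLUPs) are
    shrunken toward zero relative to the corresponding fixed-effect
    dummy estimates.
    """
    risk = np.asarray(risk, dtype=float)
    y = data.col(outcome).astype(float)
    if risk.shape != y.shape:
        raise ValueError("risk length does not match table rows")
    fixed = pd.DataFrame({"risk": risk})
    return _fit_hapc(data.table, y, fixed,
                     data.table[period_col], data.table[cohort_col])


def fit_apc_hapc(data: PanelDataset, outcome: str = "outcome",
                 age_col: str = "age", quadratic_age: bool = True,
                 cohort_col: str = "cohort", period_col: str = "period") -> HAPCFit:
    """APC hierarchical baseline: fixed linear (and optionally
    quadratic) age, crossed random intercepts for period and cohort."""
    y = data.col(outcome).astype(float)
    age = data.col(age_col).astype(float)
    age_c = age - age.mean()
    fixed = {"age": age_c}
    if quadratic_age:
        fixed["age_sq"] = age_c ** 2
    return _fit_hapc(data.table, y, pd.DataFrame(fixed),
                     data.table[period_col], data.table[cohort_col])
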