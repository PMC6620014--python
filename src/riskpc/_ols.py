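"""Shared least-squares plumbing.

All fixed-effects fits in the package go through :func:`ols`, a
minimum-norm SVD solver: on full-rank designs it agrees with the normal
equations; on rank-deficient designs it returns the minimum-norm
solution and flags the deficiency rather than silently dropping
columns.  Classical standard errors and t-based p-values come from the
pseudo-inverse of the Gram matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class OLSResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    adjusted_r_squared: float
    residual_variance: float
    rank: int
    rank_deficient: bool
    df_resid: int
    nobs: int

    @property
    def condition_number(self) -> float:
        return self._cond

    _cond: float = float("nan")


def ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSResult:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(names) != p:
        raise ValueError("names must match design columns")
    if n <= p:
        raise ValueError(f"need more rows ({n}) than parameters ({p})")
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    df_resid = n - rank
    sigma2 = rss / df_resid
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    res = OLSResult(
        params=pd.Series(coef, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        r_squared=r2,
        adjusted_r_squared=adj,
        residual_variance=sigma2,
        rank=int(rank),
        rank_deficient=rank < p,
        df_resid=int(df_resid),
        nobs=int(n),
    )
    res._cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    return res


def dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that are linear combinations of earlier ones,
    identified by rank-revealing pivoted QR."""
    X = np.asarray(X, dtype=float)
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]
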