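"""Core data containers.

Everything in this package consumes and produces :class:`PanelDataset`, a
thin wrapper around a :class:`pandas.DataFrame` holding one record per
subject (outcome, chronological age, optional calendar period and birth
cohort, and arbitrary named covariates) together with a metadata mapping
that records how the table was produced.

:class:`SimCondition` describes one slope-parameter pattern of the
simulation designs: the standardized effect sizes of chronological age
(``beta``), socioeconomic position (``alpha1``), physical activity
(``alpha2``) and, for designs with cohort structure, birth cohort
(``gamma``), plus the per-replication sample size and the RNG seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

#: Effect-size grid used when enumerating the full simulation designs.
SLOPE_GRID: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class PanelValidationError(ValueError):
    """Raised when a panel table violates a structural requirement."""


@dataclass
class SimCondition:
    """One slope-parameter pattern plus generative settings.

    Parameters
    ----------
    beta : float
        Standardized chronological-age slope.
    alpha1, alpha2 : float
        Standardized slopes of the two auxiliary risk factors
        (socioeconomic position and physical-activity count).
    gamma : float or None
        Standardized birth-cohort slope. ``None`` for cross-sectional
        designs without cohort structure.
    n : int
        Subjects per replication (at least 10).
    seed : int
        Seed for the replication's RNG stream.
    """

    beta: float
    alpha1: float
    alpha2: float
    gamma: float | None = None
    n: int = 10_000
    seed: int = 0

    def slopes(self) -> tuple[float, ...]:
        base = (self.beta, self.alpha1, self.alpha2)
        return base if self.gamma is None else base + (self.gamma,)

    def validate(self, strict_grid: bool = False) -> None:
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        for name, value in zip(("beta", "alpha1", "alpha2", "gamma"),
                               (self.beta, self.alpha1, self.alpha2, self.gamma)):
            if value is None:
                continue
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if strict_grid and not any(np.isclose(value, g) for g in SLOPE_GRID):
                raise ValueError(
                    f"{name}={value} is not on the design grid {SLOPE_GRID}"
                )

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class PanelDataset:
    """Subject-level panel table plus provenance metadata."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    def col(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"panel has no column {name!r}")
        return self.table[name].to_numpy()

    def validate(self, check_identity: bool = True) -> None:
        """Check structural invariants of the panel.

        Raises :class:`PanelValidationError` for hard violations
        (negative activity counts, empty table).  A broken
        ``cohort = period - age`` identity is reported as a warning
        listing the offending row indices, since externally supplied
        tables may legitimately carry binned or approximated cohorts.
        """
        if len(self.table) == 0:
            raise PanelValidationError("panel table is empty")
        if "activity" in self.table.columns:
            act = self.table["activity"].to_numpy()
            if (act < 0).any():
                bad = np.flatnonzero(act < 0)[:10].tolist()
                raise PanelValidationError(
                    f"activity must be non-negative; offending rows {bad}"
                )
        if check_identity and {"age", "period", "cohort"} <= set(self.table.columns):
            resid = (
                self.table["cohort"].to_numpy()
                + self.table["age"].to_numpy()
                - self.table["period"].to_numpy()
            )
            bad = np.flatnonzero(np.abs(resid) > 1e-8)
            if bad.size:
                warnings.warn(
                    "cohort != period - age for "
                    f"{bad.size} rows (first offenders: {bad[:10].tolist()})",
                    stacklevel=2,
                )


def standardize(x: np.ndarray) -> np.ndarray:
    """In-sample z-score (population denominator).

    The simulation designs inject effects on the standardized scale of
    the realized sample, so standardization always uses the sample's own
    mean and (ddof=0) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def make_panel(columns: dict[str, Iterable], meta: dict | None = None) -> PanelDataset:
    return PanelDataset(pd.DataFrame(columns), dict(meta or {}))
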