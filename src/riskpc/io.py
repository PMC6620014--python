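"""Delimited-text panel readers/writers.

Panels travel as comma-separated text with a header row, UTF-8, ``.``
decimal.  Metadata (the generating condition, generator version, draw
order) rides in a YAML sidecar next to the table
(``<name>.csv`` + ``<name>.meta.yaml``).  Writing is round-trip
stable: write-read-write produces byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import PanelDataset, PanelValidationError

log = logging.getLogger("riskpc")

#: Columns that must parse as numbers when present.
NUMERIC_COLUMNS = ("outcome", "baseline_outcome", "age", "sep", "activity",
                   "period", "cohort", "score", "sex", "comorbidities",
                   "income_ratio", "social_support", "risk")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.yaml")


def sanitize_meta(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {str(k): sanitize_meta(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [sanitize_meta(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [sanitize_meta(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_panel(data: PanelDataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.table.to_csv(path, index=False, lineterminator="\n")
    if data.meta:
        _meta_path(path).write_text(
            yaml.safe_dump(sanitize_meta(data.meta), sort_keys=True),
            encoding="utf-8")
    log.info("wrote panel %s: %d rows, %d columns",
             path, len(data.table), len(data.table.columns))
    return path


def read_panel(path, schema: dict | None = None,
               check_identity: bool = True) -> PanelDataset:
    """Read a panel table, validating structure.

    ``schema`` maps column names to dtypes and overrides inference.
    Errors name the offending row/column; a violated
    ``cohort = period - age`` identity is reported as a warning by
    :meth:`PanelDataset.validate`.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=object, keep_default_na=False,
                            skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise PanelValidationError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise PanelValidationError(f"{path}: ragged rows — {exc}") from None
    if len(table) == 0:
        raise PanelValidationError(f"{path}: table has a header but no rows")

    header_numeric = [c for c in table.columns
                      if _parses_as_number(str(c))]
    if header_numeric and len(header_numeric) == len(table.columns):
        raise PanelValidationError(
            f"{path}: first row is numeric — missing header row")

    out = {}
    for name in table.columns:
        col = table[name]
        wants_numeric = (schema or {}).get(name)
        if wants_numeric is None:
            wants_numeric = name in NUMERIC_COLUMNS or _all_numeric(col)
        if wants_numeric:
            converted = pd.to_numeric(col, errors="coerce")
            bad = converted.isna() & (col.astype(str).str.len() > 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise PanelValidationError(
                    f"{path}: non-numeric value {col.iloc[row]!r} in numeric "
                    f"column {name!r} at data row {row}")
            if converted.isna().any():
                row = int(np.flatnonzero(converted.isna().to_numpy())[0])
                raise PanelValidationError(
                    f"{path}: empty cell in numeric column {name!r} "
                    f"at data row {row}")
            # numpy's parser is correctly rounded, so write-read-write
            # round-trips bit-exactly
            out[name] = col.to_numpy(dtype=float)
        else:
            out[name] = col
    frame = pd.DataFrame(out)

    meta_path = _meta_path(path)
    meta = {}
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text(encoding="utf-8")) or {}
    ds = PanelDataset(frame, meta)
    ds.validate(check_identity=check_identity)
    log.info("read panel %s: %d rows in, %d kept, 0 dropped",
             path, len(frame), len(frame))
    return ds


def _parses_as_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def _all_numeric(col: pd.Series) -> bool:
    return bool(col.map(lambda v: _parses_as_number(str(v))).all())
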