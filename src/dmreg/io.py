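"""Reading and writing angle tables and analysis reports.

Angle tables are CSV files with two named columns ``u`` and ``v`` (any
case), optionally preceded by a label column.  Angles may be stored in
degrees or radians; the library works in radians internally and converts
at this boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .exceptions import InvalidInputError, InvalidParameterError
from .model import AnglePairs

__all__ = ["read_angle_table", "write_angle_table", "to_radians", "to_degrees"]

_UNITS = ("radians", "degrees")


def _check_unit(unit: str) -> str:
    unit = unit.lower()
    if unit not in _UNITS:
        raise InvalidParameterError(f"unit must be one of {_UNITS}, got {unit!r}")
    return unit


def to_radians(values, unit: str):
    """Convert angles in ``unit`` to radians (no wrapping)."""
    values = np.asarray(values, dtype=float)
    return np.deg2rad(values) if _check_unit(unit) == "degrees" else values


def to_degrees(values, unit: str):
    """Convert radians to ``unit``."""
    values = np.asarray(values, dtype=float)
    return np.rad2deg(values) if _check_unit(unit) == "degrees" else values


def read_angle_table(path, unit: str = "radians") -> AnglePairs:
    """Read a two-column (u, v) angle table from CSV.

    Columns named ``u`` and ``v`` (case-insensitive) are required; a
    ``label`` column (or any single extra leading column) provides row
    labels.  Values are converted to radians per ``unit`` and wrapped to
    [0, 2*pi).  Parse problems are reported with the offending row and
    column.
    """
    unit = _check_unit(unit)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: file is empty") from exc
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [name for name in ("u", "v") if name not in cols]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")
    parsed = {}
    for name in ("u", "v"):
        raw = df[cols[name]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1  # 1-based data row
            raise InvalidInputError(
                f"{path}: non-numeric value {raw.iloc[row - 1]!r} in column "
                f"{cols[name]!r} at data row {row}"
            )
        parsed[name] = vals.to_numpy(dtype=float)
    label_cols = [c for c in df.columns if c.lower().strip() not in ("u", "v")]
    labels = tuple(str(x) for x in df[label_cols[0]]) if label_cols else None
    return AnglePairs(
        to_radians(parsed["u"], unit), to_radians(parsed["v"], unit), labels
    )


def write_angle_table(data: AnglePairs, path, unit: str = "radians") -> None:
    """Write an angle table to CSV in the requested unit."""
    unit = _check_unit(unit)
    out = {}
    if data.labels is not None:
        out["label"] = list(data.labels)
    out["u"] = to_degrees(wrap_angle(data.u), unit)
    out["v"] = to_degrees(wrap_angle(data.v), unit)
    pd.DataFrame(out).to_csv(path, index=False)
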