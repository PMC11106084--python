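"""Schema-validated CSV readers/writers and JSON report assembly.

All file interfaces are plain text: CSV for tables, JSON for reports.
Readers validate column presence, dtypes and value ranges and report the
offending row numbers (1-based, counting the header as row 1) in the error
message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_pit_table",
    "read_foci_table",
    "read_colony_table",
    "write_table",
    "write_json_report",
]


class SchemaError(ValueError):
    """A CSV input violated its schema; the message lists row numbers."""


def _bad_rows(mask: pd.Series) -> str:
    rows = (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # +2: header + 1-based
    return ", ".join(map(str, rows[:20])) + ("…" if len(rows) > 20 else "")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check(df: pd.DataFrame, column: str, ok: pd.Series, what: str, path) -> None:
    if not ok.all():
        raise SchemaError(
            f"{path}: column {column!r} {what} in rows {_bad_rows(~ok)}"
        )


def read_pit_table(path) -> pd.DataFrame:
    """Read (dilution, field_id, pit_count) etch-pit counts per field."""
    df = pd.read_csv(path)
    _require_columns(df, ["dilution", "field_id", "pit_count"], path)
    _check(df, "dilution", df["dilution"].between(0, 1), "outside (0, 1]", path)
    _check(df, "dilution", df["dilution"] > 0, "must be positive", path)
    _check(df, "pit_count", df["pit_count"] >= 0, "negative", path)
    _check(
        df, "pit_count",
        df["pit_count"] == df["pit_count"].astype(int),
        "not an integer", path,
    )
    return df


def read_foci_table(path) -> pd.DataFrame:
    """Read (dilution, nucleus_id, focus_count, nucleus_area_um2)."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["dilution", "nucleus_id", "focus_count", "nucleus_area_um2"], path
    )
    _check(df, "dilution", (df["dilution"] > 0) & (df["dilution"] <= 1),
           "outside (0, 1]", path)
    _check(df, "focus_count", df["focus_count"] >= 0, "negative", path)
    _check(df, "nucleus_area_um2", df["nucleus_area_um2"] > 0, "non-positive", path)
    return df


def read_colony_table(path) -> pd.DataFrame:
    """Read (dilution, plated, colonies) colony-formation counts.

    An optional ``dish_id`` column is preserved; an optional ``dose_gy``
    column (pre-converted input) is preserved as well.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["dilution", "plated", "colonies"], path)
    _check(df, "dilution", (df["dilution"] > 0) & (df["dilution"] <= 1),
           "outside (0, 1]", path)
    _check(df, "plated", df["plated"] > 0, "non-positive", path)
    _check(df, "colonies", df["colonies"] >= 0, "negative", path)
    _check(df, "colonies", df["colonies"] <= df["plated"],
           "exceeds plated cells", path)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a CSV that round-trips through the corresponding reader."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def write_json_report(path, payload: dict, *, config: dict | None = None,
                      seed: int | None = None) -> Path:
    """Write a JSON report with a provenance block (config echo, version, seed)."""
    from . import __version__

    report = {
        "provenance": {
            "package": "dartdose",
            "version": __version__,
            "seed": seed,
            "config": config or {},
        },
        **payload,
    }

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"cannot serialize {type(obj)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_default) + "\n")
    return path
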