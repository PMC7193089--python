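"""Reading, validating and writing cohort tables.

A cohort table is a pandas DataFrame with one row per RoI (region of
interest), identifier columns ``tumor_id``, ``roi_id``, ``relapse`` and the
nine marker columns holding positive fractions in [0, 1].  Missing marker
values (tissue lost during staining) are NaN in memory and empty cells on
disk.  All on-disk interchange is TSV with a header; fractions are written
with six decimals so repeated runs are byte-stable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ID_COLUMNS, MARKERS

FLOAT_FORMAT = "%.6f"


class CohortTableError(ValueError):
    """Malformed cohort table (bad columns, duplicate ids, out-of-range values)."""


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate identifier and marker columns; return the table in canonical column order.

    Raises :class:`CohortTableError` on duplicate ``roi_id`` or any marker
    value outside [0, 1]; unknown marker-like columns are dropped with a
    warning.  Row order is preserved.
    """
    missing_ids = [c for c in ID_COLUMNS if c not in table.columns]
    if missing_ids:
        raise CohortTableError(f"missing required columns: {missing_ids}")
    present_markers = [m for m in MARKERS if m in table.columns]
    if not present_markers:
        raise CohortTableError("no panel marker columns present")
    extra = [
        c for c in table.columns
        if c not in ID_COLUMNS and c not in MARKERS
    ]
    if extra:
        warnings.warn(f"ignoring unknown columns: {extra}", stacklevel=2)
    dup = table["roi_id"][table["roi_id"].duplicated()]
    if len(dup):
        raise CohortTableError(f"duplicate roi_id values: {sorted(set(dup))}")
    for m in present_markers:
        col = pd.to_numeric(table[m], errors="coerce")
        bad = table.index[(col < 0) | (col > 1)]
        if len(bad):
            row = bad[0]
            raise CohortTableError(
                f"value out of [0, 1] at row {row!r}, column {m!r}: {table.loc[row, m]!r}"
            )
    out = table[list(ID_COLUMNS) + present_markers].copy()
    out[present_markers] = out[present_markers].astype(float)
    out["relapse"] = out["relapse"].astype(int)
    out["tumor_id"] = out["tumor_id"].astype(str)
    out["roi_id"] = out["roi_id"].astype(str)
    return out


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV/CSV (separator sniffed from the extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={"tumor_id": str, "roi_id": str})
    return validate_cohort_table(raw)


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as TSV; NaN marker cells become empty fields."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Panel markers present in the table, in canonical order."""
    return [m for m in MARKERS if m in table.columns]


def marker_matrix(table: pd.DataFrame) -> np.ndarray:
    """Marker values as a float array (rows = RoIs, columns = panel order)."""
    return table[marker_columns(table)].to_numpy(dtype=float)
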