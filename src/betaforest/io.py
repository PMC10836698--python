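"""CSV readers/writers with fixed schemas for the pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .bootstrap import DRAW_TABLE_COLUMNS
from .errors import SchemaError
from .pooling import POOLED_TABLE_COLUMNS
from .ranges import RANGE_TABLE_COLUMNS
from .regression import FIT_TABLE_COLUMNS

SCHEMAS = {
    "fit": FIT_TABLE_COLUMNS,
    "pooled": POOLED_TABLE_COLUMNS,
    "ranges": RANGE_TABLE_COLUMNS,
    "draws": DRAW_TABLE_COLUMNS,
}

#: Columns that must parse as numbers, per schema.
_NUMERIC = {
    "fit": ["beta", "se", "t", "p", "ci_lower", "ci_upper", "n_obs"],
    "pooled": ["m", "beta_pooled", "se_pooled", "df_rubin", "ci_lower", "ci_upper"],
    "ranges": ["beta_pooled", "est_min", "est_max", "ci_outer_lower", "ci_outer_upper"],
    "draws": ["beta", "replicate"],
}


def read_table(path, expected_schema: Optional[Sequence[str]] = None, schema_name: Optional[str] = None) -> pd.DataFrame:
    """Read a CSV table, checking that the expected columns are present.

    ``expected_schema`` is an explicit column list; ``schema_name`` selects
    one of the built-in stage schemas ('fit', 'pooled', 'ranges', 'draws').
    Extra columns are preserved.  Empty fields and "NA" parse as missing.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if schema_name is not None:
        expected_schema = SCHEMAS[schema_name]
    if expected_schema is not None:
        missing = [c for c in expected_schema if c not in table.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {missing}")
    if schema_name is not None:
        for col in _NUMERIC[schema_name]:
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError):
                bad = pd.to_numeric(table[col], errors="coerce")
                row = int(bad[bad.isna() & table[col].notna()].index[0])
                raise SchemaError(
                    f"{path}: unparseable numeric value in column {col!r}, row {row}"
                ) from None
    if schema_name == "fit" and "error" in table.columns:
        table["error"] = table["error"].fillna("")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a table as CSV without the index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_name_list(value: str) -> list[str]:
    """Parse an outcome/predictor list: comma-separated names, or ``@file``
    pointing at a one-name-per-line text file."""
    if value.startswith("@"):
        lines = Path(value[1:]).read_text().splitlines()
        return [ln.strip() for ln in lines if ln.strip()]
    return [v.strip() for v in value.split(",") if v.strip()]
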