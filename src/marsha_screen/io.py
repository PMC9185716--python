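"""Reading and writing respondent cohorts as delimited text.

Cohorts are UTF-8 comma-delimited files with a header row: one row per
respondent, item columns coded 0-3 with blank cells for skipped items, plus
demographic and QC-metadata columns.  Writing is deterministic (fixed column
order, fixed float formatting) so identical configurations produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import OPEN_TEXT_COLUMNS, REQUIRED_COLUMNS
from .schema import DEFAULT_SCHEMA


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a respondent cohort CSV; blank item cells become missing."""
    df = pd.read_csv(path, dtype={"zip": str, "state": str, "record_id": str})
    for col in DEFAULT_SCHEMA.item_ids:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in OPEN_TEXT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with a canonical column order."""
    lead = [c for c in REQUIRED_COLUMNS if c in df.columns]
    items = [c for c in DEFAULT_SCHEMA.item_ids if c in df.columns]
    rest = [c for c in df.columns if c not in lead and c not in items]
    out = df.loc[:, lead + rest + items]
    out.to_csv(path, index=False, float_format="%.4f")
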