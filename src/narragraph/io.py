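"""Tolerant subject-table reader (CSV or XLSX).

Study metadata often arrives as a spreadsheet with ad-hoc headers; this
reader normalizes column names and applies a user column map so that the
rest of the pipeline can rely on the canonical layout
(subject_id, asrs_01..asrs_18, age, iq, education_years, bdi,
stai_state, stai_trait, upps_total).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _normalize(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_").replace("-", "_")


def read_subject_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a subject metadata table from CSV or XLSX.

    ``column_map`` maps source column names (matched after whitespace /
    case normalization) to canonical names. Unmapped columns keep their
    normalized names.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    df.columns = [_normalize(c) for c in df.columns]
    if column_map:
        mapping = {_normalize(k): v for k, v in column_map.items()}
        df = df.rename(columns=mapping)
    return df
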