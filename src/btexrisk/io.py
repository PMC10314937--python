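"""Campaign-table input/output.

The canonical on-disk form of a sampling campaign is a UTF-8 CSV with a
mandatory header and one row per shift sample:

    subject_id, workstation, season, analyte, concentration_mg_m3,
    duration_min, below_lod, et_h_day, ef_d_yr, ed_yr, bw_kg

``below_lod`` is 0/1; decimal separator is ".".
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exposure import SEASONS, WORKSTATIONS

CAMPAIGN_COLUMNS = [
    "subject_id",
    "workstation",
    "season",
    "analyte",
    "concentration_mg_m3",
    "duration_min",
    "below_lod",
    "et_h_day",
    "ef_d_yr",
    "ed_yr",
    "bw_kg",
]

_NUMERIC = ["concentration_mg_m3", "duration_min", "et_h_day", "ef_d_yr", "ed_yr", "bw_kg"]


def validate_campaign(table: pd.DataFrame) -> pd.DataFrame:
    """Check the column contract of a campaign table; returns the table."""
    missing = [c for c in CAMPAIGN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"campaign table missing columns: {missing}")
    bad_ws = set(table["workstation"]) - set(WORKSTATIONS)
    if bad_ws:
        raise ValueError(f"unknown workstations: {sorted(bad_ws)}")
    bad_season = set(table["season"]) - set(SEASONS)
    if bad_season:
        raise ValueError(f"unknown seasons: {sorted(bad_season)}")
    if (table["concentration_mg_m3"] < 0).any():
        raise ValueError("negative concentrations in campaign table")
    if not table["duration_min"].between(1, 1440).all():
        raise ValueError("sample durations outside [1, 1440] min")
    return table


def read_campaign(path: str | Path) -> pd.DataFrame:
    """Read and validate a campaign CSV."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    table["below_lod"] = table["below_lod"].astype(int)
    for col in _NUMERIC:
        table[col] = pd.to_numeric(table[col])
    return validate_campaign(table)


def write_campaign(table: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a campaign table as CSV (no index column)."""
    validate_campaign(table)
    table.to_csv(path, index=False, columns=CAMPAIGN_COLUMNS)
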