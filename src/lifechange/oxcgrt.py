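"""Regional policy/threat index series: window averages and dataset joins.

Input follows the shape of public government-response tracker exports: one
row per (region, date) with four index columns.  Column aliases used by the
public OxCGRT CSVs are accepted and renamed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

INDEX_COLS = [
    "containment_health_index",
    "economic_support_index",
    "confirmed_cases_per_million",
    "confirmed_deaths_per_million",
]

_ALIASES = {
    "RegionCode": "region",
    "RegionName": "region",
    "Date": "date",
    "ContainmentHealthIndex": "containment_health_index",
    "EconomicSupportIndex": "economic_support_index",
    "ConfirmedCasesPerMillion": "confirmed_cases_per_million",
    "ConfirmedDeathsPerMillion": "confirmed_deaths_per_million",
}


def load_series(path: str | Path) -> pd.DataFrame:
    """Read a per-(region, date) index CSV, normalising column names."""
    frame = pd.read_csv(path)
    frame = frame.rename(columns={k: v for k, v in _ALIASES.items() if k in frame.columns})
    required = ["region", "date"] + INDEX_COLS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"index series is missing columns: {missing}")
    return frame


def window_average(
    series: pd.DataFrame, start_date: str, end_date: str
) -> pd.DataFrame:
    """Per-region mean of each index over an inclusive date window.

    Regions with no dates inside the window are reported with missing
    values (and logged) rather than dropped.
    """
    try:
        dates = pd.to_datetime(series["date"], format="ISO8601")
        start = pd.Timestamp(start_date)
        end = pd.Timestamp(end_date)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed date: {exc}") from exc
    if start > end:
        raise ValueError(f"start date {start_date} is after end date {end_date}")
    inside = series[(dates >= start) & (dates <= end)]
    means = inside.groupby("region")[INDEX_COLS].mean()
    all_regions = pd.Index(sorted(series["region"].unique()), name="region")
    means = means.reindex(all_regions)
    empty = means.index[means[INDEX_COLS[0]].isna()].tolist()
    if empty:
        logger.warning("regions with no dates in window [%s, %s]: %s",
                       start_date, end_date, empty)
    return means


def join_indices(
    frame: pd.DataFrame,
    region_means: pd.DataFrame,
    region_col: str = "state",
    country_col: str = "country",
) -> pd.DataFrame:
    """Left-join per-region index averages onto US participant rows.

    Non-US rows receive missing index columns by design (regional series
    are only defined for US states here); unmatched US region codes are
    logged.
    """
    out = frame.copy()
    us = out[country_col] == "US" if country_col in out.columns else pd.Series(True, index=out.index)
    joined = out.loc[us, [region_col]].join(region_means, on=region_col)
    unmatched = sorted(
        joined.loc[joined[INDEX_COLS[0]].isna(), region_col].dropna().unique().tolist()
    )
    if unmatched:
        logger.warning("US region codes with no index data: %s", unmatched)
    for col in INDEX_COLS:
        out[col] = pd.NA
        out.loc[us, col] = joined[col]
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out
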