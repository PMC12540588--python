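"""Reading weather/crime inputs and assembling the daily analysis panel.

The study calendar drops February 29 so that whole-year periods have exactly
365 rows per year (a five-year study spans 1,825 days).  Weather must cover
every calendar day — gaps are a hard error, never imputed.  Incident records
are filtered case-insensitively to the violent categories and aggregated to
daily counts, with days that saw no incident carried as explicit zeros.

CSV dialects
------------
Weather:   ``date,apparent_temperature_mean,temperature_mean,precipitation_sum``
           (ISO dates, degrees Celsius, millimetres).
Incidents: ``date,time,category,disadvantaged`` — ``time`` and
           ``disadvantaged`` (0/1/empty) are optional.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ("date", "apparent_temperature_mean", "temperature_mean", "precipitation_sum")
#: case-folded default violent-crime categories
VIOLENT_CATEGORIES = frozenset({"homicide", "assault", "robbery"})

APPARENT_TEMP_BOUNDS = (-40.0, 60.0)  # sanity window, °C


class IngestError(ValueError):
    """Raised for invalid or inconsistent input data."""


def study_calendar(start: "str | pd.Timestamp", end: "str | pd.Timestamp") -> pd.DatetimeIndex:
    """All dates in [start, end] with every February 29 excluded."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise IngestError(f"study end {end.date()} precedes start {start.date()}")
    days = pd.date_range(start, end, freq="D")
    keep = ~((days.month == 2) & (days.day == 29))
    return days[keep]


def read_weather(path: "str | Path") -> pd.DataFrame:
    """Read and validate a daily weather CSV.

    Returns a date-sorted frame with a ``date`` column of datetime64 dtype.
    Duplicate dates, unparseable dates, negative precipitation and apparent
    temperatures outside (−40, 60) °C are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"weather file {path} missing required column(s): {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise IngestError(f"weather file {path}: unparseable date ({exc})") from exc
    dup = df["date"][df["date"].duplicated()]
    if len(dup):
        raise IngestError(f"weather file {path}: duplicated date(s) {sorted(d.date().isoformat() for d in dup.unique())}")
    if (df["precipitation_sum"] < 0).any():
        bad = df.loc[df["precipitation_sum"] < 0, "date"].iloc[0]
        raise IngestError(f"weather file {path}: negative precipitation on {bad.date()}")
    lo, hi = APPARENT_TEMP_BOUNDS
    out_of_range = ~df["apparent_temperature_mean"].between(lo, hi)
    if out_of_range.any():
        bad = df.loc[out_of_range, "date"].iloc[0]
        raise IngestError(f"weather file {path}: apparent temperature outside ({lo}, {hi}) °C on {bad.date()}")
    if df[list(WEATHER_COLUMNS[1:])].isna().any().any():
        raise IngestError(f"weather file {path}: missing weather values are not allowed")
    return df.sort_values("date").reset_index(drop=True)


def read_incidents(
    path: "str | Path",
    violent_categories: Iterable[str] = VIOLENT_CATEGORIES,
    allow_bad_rows: bool = False,
) -> pd.DataFrame:
    """Read an incident CSV and keep only violent-category records.

    Category matching is case-insensitive exact match.  Rows whose date cannot
    be parsed raise unless ``allow_bad_rows``, in which case they are dropped
    and counted in the log.
    """
    violent = {c.casefold() for c in violent_categories}
    df = pd.read_csv(path, dtype={"category": "string"})
    for col in ("time", "disadvantaged"):
        if col not in df.columns:
            df[col] = pd.NA
    required = [c for c in ("date", "category") if c not in df.columns]
    if required:
        raise IngestError(f"incident file {path} missing required column(s): {required}")
    if df.empty:
        logger.warning("incident file %s is empty", path)
        df["date"] = pd.to_datetime(df["date"])
        return df[["date", "time", "category", "disadvantaged"]]
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna() | df["category"].isna() | (df["category"].str.strip() == "")
    if bad.any():
        if not allow_bad_rows:
            raise IngestError(
                f"incident file {path}: {int(bad.sum())} unparseable row(s); "
                "pass allow_bad_rows=True to drop them"
            )
        logger.warning("incident file %s: dropping %d unparseable row(s)", path, int(bad.sum()))
        df, dates = df[~bad], dates[~bad]
    df = df.assign(date=dates)
    keep = df["category"].str.casefold().isin(violent)
    out = df.loc[keep, ["date", "time", "category", "disadvantaged"]].reset_index(drop=True)
    logger.info("incident file %s: retained %d of %d rows in violent categories %s",
                path, len(out), len(df), sorted(violent))
    return out


def build_panel(
    weather: pd.DataFrame,
    incidents: pd.DataFrame,
    study_start: "str | pd.Timestamp",
    study_end: "str | pd.Timestamp",
    site_id: str = "site",
) -> pd.DataFrame:
    """Assemble the one-row-per-study-day analysis panel for one site.

    Weather must cover every study-calendar day.  Incidents outside the
    period, and incidents falling on an excluded leap day, are dropped with a
    logged count.  ``disadvantaged`` values other than truthy 1/True count
    toward the total only.
    """
    cal = study_calendar(study_start, study_end)
    widx = pd.DatetimeIndex(weather["date"])
    missing = cal.difference(widx)
    if len(missing):
        raise IngestError(
            f"weather missing for {len(missing)} study day(s), first {missing[0].date()}"
        )
    panel = (
        weather.set_index("date")
        .loc[cal, list(WEATHER_COLUMNS[1:])]
        .copy()
    )
    panel.index.name = "date"

    dates = pd.DatetimeIndex(incidents["date"]).normalize() if len(incidents) else pd.DatetimeIndex([])
    in_cal = dates.isin(cal)
    n_dropped = int((~in_cal).sum())
    if n_dropped:
        n_leap = int(((dates.month == 2) & (dates.day == 29) & (dates >= cal[0]) & (dates <= cal[-1])).sum())
        logger.info("dropped %d incident(s) outside the study calendar (%d on excluded leap days)",
                    n_dropped, n_leap)
    kept = incidents.loc[np.asarray(in_cal)]
    kept_dates = dates[in_cal]
    counts = pd.Series(1, index=kept_dates).groupby(level=0).size() if len(kept) else pd.Series(dtype=int)
    disadv_mask = kept["disadvantaged"].fillna(0).astype(float).to_numpy() == 1 if len(kept) else np.array([], bool)
    dis_counts = (
        pd.Series(disadv_mask.astype(int), index=kept_dates).groupby(level=0).sum()
        if len(kept) else pd.Series(dtype=int)
    )
    panel["crime_count"] = counts.reindex(cal, fill_value=0).astype(int)
    panel["crime_count_disadvantaged"] = dis_counts.reindex(cal, fill_value=0).astype(int)
    panel.attrs["site_id"] = site_id
    return panel


def write_panel(panel: pd.DataFrame, path: "str | Path") -> None:
    """Serialize a panel (classified or not) to CSV, dates as ISO strings."""
    out = panel.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=True, date_format="%Y-%m-%d")


def read_panel(path: "str | Path") -> pd.DataFrame:
    """Re-read a panel written by :func:`write_panel`, restoring dtypes."""
    panel = pd.read_csv(path, index_col="date", parse_dates=["date"])
    for col in ("wet", "weekend", "baseline_complete"):
        if col in panel.columns:
            panel[col] = panel[col].astype(bool)
    for col in ("crime_count", "crime_count_disadvantaged"):
        if col in panel.columns:
            panel[col] = panel[col].astype(int)
    return panel
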