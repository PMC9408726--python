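"""Readers/writers for the tabular formats the pipeline touches.

All files are plain comma-separated CSV with a header row, UTF-8 encoded,
ISO-8601 calendar dates (no times, no time zones).  Formats:

* weather:    ``date,station_id,region,tmin,tmax,tmean,dewpoint`` (deg C)
* alerts:     ``start_date,end_date,county,product``
* region map: ``county,region``
* HRI counts: ``date,region,count[,censored]``
* results:    one row per (region, definition) model fit

Alert intervals are date-inclusive on both ends, matching how heat
advisories are published as whole days.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DuplicateRecordError, MappingError, SchemaError

#: canonical name -> default CSV column name
DEFAULT_WEATHER_SCHEMA = {
    "date": "date",
    "station_id": "station_id",
    "region": "region",
    "tmin": "tmin",
    "tmax": "tmax",
    "tmean": "tmean",
    "dewpoint": "dewpoint",
}

ALERT_PRODUCTS = frozenset({"advisory", "excessive_heat_warning"})

RESULT_COLUMNS = [
    "region",
    "definition_id",
    "metric",
    "duration",
    "threshold_type",
    "intensity",
    "threshold_c",
    "hw_days",
    "rr",
    "ci_lo",
    "ci_hi",
    "aic",
    "theta",
]

_NUMERIC_WEATHER = ["tmin", "tmax", "tmean", "dewpoint"]


def summer_dates(years: Iterable[int], start=(5, 1), end=(9, 30)) -> pd.DatetimeIndex:
    """Daily index covering the summer season (default 1 May - 30 Sep) of each year."""
    pieces = [
        pd.date_range(pd.Timestamp(y, *start), pd.Timestamp(y, *end), freq="D")
        for y in sorted(set(years))
    ]
    return pieces[0].append(pieces[1:]) if len(pieces) > 1 else pieces[0]


def read_daily_weather(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a GHCN-D-like station weather CSV.

    Returns one row per (station, date), sorted ascending by date then
    station.  Unparseable numeric cells become NaN.

    Raises
    ------
    SchemaError
        if a required column is missing (the message names it).
    DuplicateRecordError
        if the same (station, date) appears twice.
    """
    schema = {**DEFAULT_WEATHER_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"weather file {path} missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in schema.items()})[list(schema)]
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    for col in _NUMERIC_WEATHER:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dups = df.duplicated(subset=["station_id", "date"])
    if dups.any():
        first = df.loc[dups.idxmax()]
        raise DuplicateRecordError(
            f"duplicate record for station {first.station_id!r} on {first.date.date()}"
        )
    return df.sort_values(["date", "station_id"], kind="stable").reset_index(drop=True)


def aggregate_to_region(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse station-days to one row per (region, date).

    Each field is the unweighted arithmetic mean over the stations reporting
    that field that day; a field nobody reports is NaN.  Empty input yields
    an empty frame with the output columns.
    """
    out_cols = ["region", "date"] + _NUMERIC_WEATHER
    if len(records) == 0:
        return pd.DataFrame(columns=out_cols)
    grouped = (
        records.groupby(["region", "date"], sort=True)[_NUMERIC_WEATHER]
        .mean()
        .reset_index()
    )
    return grouped[out_cols]


def read_region_map(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("county", "region"):
        if col not in df.columns:
            raise SchemaError(f"region map {path} missing required column: {col}")
    return dict(zip(df["county"], df["region"]))


def read_alerts(path) -> pd.DataFrame:
    """Read NWS heat-product intervals: start_date,end_date,county,product."""
    df = pd.read_csv(path, dtype=str)
    for col in ("start_date", "end_date", "county", "product"):
        if col not in df.columns:
            raise SchemaError(f"alerts file {path} missing required column: {col}")
    df["start_date"] = pd.to_datetime(df["start_date"], format="ISO8601").dt.normalize()
    df["end_date"] = pd.to_datetime(df["end_date"], format="ISO8601").dt.normalize()
    bad = df["start_date"] > df["end_date"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"alert interval ends before it starts: {row.to_dict()}")
    unknown = set(df["product"]) - ALERT_PRODUCTS
    if unknown:
        raise ValueError(f"unknown alert product(s): {sorted(unknown)}")
    return df


def expand_alerts(
    intervals: pd.DataFrame,
    region_map: Mapping[str, str],
    window: pd.DatetimeIndex,
) -> dict[str, pd.Series]:
    """Convert alert intervals to daily binary NWS_HW flags per region.

    A day is flagged 1 for a region iff at least one interval, mapped through
    a county in that region, covers it (both endpoints inclusive).  Advisories
    and excessive-heat warnings both count; overlaps stay binary.  Every
    region appearing in the map gets a series over the full window.
    """
    if len(window) == 0:
        raise ValueError("expand_alerts: empty window")
    window = pd.DatetimeIndex(window)
    flags = {
        region: pd.Series(0, index=window, dtype="int8", name="nws_hw")
        for region in sorted(set(region_map.values()))
    }
    if len(intervals):
        unmapped = sorted(set(intervals["county"]) - set(region_map))
        if unmapped:
            raise MappingError(f"counties absent from region map: {', '.join(unmapped)}")
        for rec in intervals.itertuples(index=False):
            days = pd.date_range(rec.start_date, rec.end_date, freq="D")
            region = region_map[rec.county]
            flags[region].loc[flags[region].index.intersection(days)] = 1
    return flags


def read_hri(path) -> pd.DataFrame:
    """Read daily HRI counts: date,region,count[,censored]; absent censored => False."""
    df = pd.read_csv(path)
    for col in ("date", "region", "count"):
        if col not in df.columns:
            raise SchemaError(f"HRI file {path} missing required column: {col}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    df["count"] = pd.to_numeric(df["count"]).astype(int)
    if "censored" in df.columns:
        df["censored"] = df["censored"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        df["censored"] = False
    return df[["date", "region", "count", "censored"]]


def write_results(fits: pd.DataFrame | Iterable[Mapping], path) -> None:
    """Write tidy model results (one row per region x definition).

    Raises ValueError on an empty collection; round-trips through
    :func:`read_results`.
    """
    df = pd.DataFrame(fits)
    if len(df) == 0:
        raise ValueError("write_results: no fits to write")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results missing column(s): {', '.join(missing)}")
    df[RESULT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results file {path} missing column(s): {', '.join(missing)}")
    return df
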