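"""Heat-wave definition grammar, percentile thresholds, and run-length flagging.

A definition is (heat metric, duration, threshold type, intensity).  Relative
thresholds are percentiles of a long summer climatology; absolute thresholds
are fixed deg C cutoffs.  Exceedance is strict (value > threshold; ties do
not count).  For k+ duration, a day is a heat-wave day iff it belongs to a
maximal run of consecutive exceedance days of length >= k; runs break at
missing values and at season boundaries — exposure does not accumulate
across the winter gap between 30 Sep and the following 1 May.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

METRICS = ("mean", "max", "min", "apparent_max")
METRIC_COLUMNS = {"mean": "tmean", "max": "tmax", "min": "tmin", "apparent_max": "at_max"}


@dataclass(frozen=True)
class HWDefinition:
    """One row of the definition grammar.

    ``min_run`` is 1 for single-day definitions, else the minimum run length
    (2 for "2+ consecutive days", 3 for "3+").  ``intensity`` is a percentile
    for relative definitions and a deg C cutoff for absolute ones.
    """

    id: str
    metric: str
    min_run: int
    threshold_type: str  # "relative" | "absolute"
    intensity: float

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.threshold_type not in ("relative", "absolute"):
            raise ValueError(f"unknown threshold type {self.threshold_type!r}")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")

    @property
    def duration(self) -> str:
        return "1-day" if self.min_run == 1 else f"{self.min_run}+ consecutive"


# (min_run, percentile) grid shared by the mean/max/min temperature blocks
_PCT_GRID = [(2, 99), (3, 99), (2, 98), (3, 98), (2, 95), (3, 95), (2, 90), (3, 90)]


def standard_definitions() -> list[HWDefinition]:
    """The standard 28-definition set.

    HW_01-08 mean temperature, HW_09-16 maximum temperature and HW_18-25
    minimum temperature, each over the (2+/3+ days) x (99/98/95/90th
    percentile) grid; HW_17 a single day of maximum temperature above an
    absolute 35 deg C; HW_26-28 single-day maximum apparent temperature
    above the 95/90/85th percentiles.
    """
    defs: list[HWDefinition] = []
    for start, metric in ((1, "mean"), (9, "max"), (18, "min")):
        for i, (k, p) in enumerate(_PCT_GRID):
            defs.append(HWDefinition(f"HW_{start + i:02d}", metric, k, "relative", float(p)))
    defs.append(HWDefinition("HW_17", "max", 1, "absolute", 35.0))
    for i, p in enumerate((95, 90, 85)):
        defs.append(HWDefinition(f"HW_{26 + i:02d}", "apparent_max", 1, "relative", float(p)))
    return sorted(defs, key=lambda d: d.id)


def compute_threshold(baseline, percentile: float, method: str = "linear") -> float:
    """Percentile of the baseline values; the default method interpolates
    linearly between order statistics (position h = (n-1)*p/100 + 1).
    Missing values are dropped; an empty baseline is an error."""
    vals = np.asarray(baseline, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("compute_threshold: empty baseline after dropping missing values")
    return float(np.percentile(vals, percentile, method=method))


def compute_thresholds(
    baseline: pd.DataFrame, definitions: Iterable[HWDefinition], method: str = "linear"
) -> dict[tuple[str, str], float]:
    """Resolve every definition to a deg C threshold per region.

    ``baseline`` holds the climatology: one row per (region, date) with the
    metric columns (tmean/tmax/tmin/at_max) over the baseline summer days.
    Absolute definitions pass their intensity through unchanged.
    """
    thresholds: dict[tuple[str, str], float] = {}
    for region, sub in baseline.groupby("region", sort=True):
        for d in definitions:
            if d.threshold_type == "absolute":
                thresholds[(region, d.id)] = float(d.intensity)
            else:
                thresholds[(region, d.id)] = compute_threshold(
                    sub[METRIC_COLUMNS[d.metric]], d.intensity, method=method
                )
    return thresholds


def flag_days(
    dates, values, definition: HWDefinition, threshold: float
) -> pd.Series:
    """Binary heat-wave flags on the ordered study window.

    Exceedance is strict (value > threshold).  A day is flagged iff it lies
    in a maximal run of consecutive exceedance days of length >=
    ``definition.min_run``; runs terminate at missing values and wherever
    consecutive dates are more than one calendar day apart (the off-season
    gap).
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) != len(values):
        raise AlignmentError(
            f"flag_days: {len(dates)} dates but {len(values)} values for {definition.id}"
        )
    if len(dates) == 0:
        return pd.Series([], index=dates, dtype="int8", name=definition.id)
    with np.errstate(invalid="ignore"):
        exceed = values > threshold  # NaN -> False
    day_gap = np.empty(len(dates), dtype=bool)
    day_gap[0] = True
    day_gap[1:] = np.diff(dates.values).astype("timedelta64[D]") != np.timedelta64(1, "D")
    # label maximal runs: a new group starts on a gap or a flip of exceedance
    flip = np.empty(len(dates), dtype=bool)
    flip[0] = True
    flip[1:] = exceed[1:] != exceed[:-1]
    group = np.cumsum(day_gap | flip)
    run_len = pd.Series(group).groupby(group).transform("size").to_numpy()
    flags = exceed & (run_len >= definition.min_run)
    return pd.Series(flags.astype("int8"), index=dates, name=definition.id)


def flag_all(
    weather: pd.DataFrame,
    definitions: Iterable[HWDefinition],
    thresholds: Mapping[tuple[str, str], float],
) -> tuple[dict[tuple[str, str], pd.Series], pd.DataFrame]:
    """Flag every definition in every region.

    ``weather`` is the regional study-window frame with metric columns.
    Returns ``(flags, counts)``: flags keyed by (region, definition id), and
    a tidy frame of flagged-day counts.  A definition with no resolvable
    threshold raises KeyError naming it.
    """
    definitions = list(definitions)
    flags: dict[tuple[str, str], pd.Series] = {}
    rows = []
    for region, sub in weather.groupby("region", sort=True):
        sub = sub.sort_values("date")
        for d in definitions:
            key = (region, d.id)
            if key not in thresholds:
                raise KeyError(f"no threshold resolved for definition {d.id} in region {region}")
            series = flag_days(sub["date"], sub[METRIC_COLUMNS[d.metric]], d, thresholds[key])
            flags[key] = series
            rows.append(
                {
                    "region": region,
                    "definition_id": d.id,
                    "threshold_c": thresholds[key],
                    "hw_days": int(series.sum()),
                }
            )
    return flags, pd.DataFrame(rows)
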