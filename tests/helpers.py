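"""Shared independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_force_flags(dates, values, min_run: int, threshold: float) -> np.ndarray:
    """Day-by-day heat-wave flagging by explicit neighbourhood expansion.

    A day is flagged iff, walking outward through calendar-contiguous
    exceedance days, the surrounding maximal run reaches ``min_run``.
    Deliberately naive and loop-based, independent of the vectorised
    run-labelling implementation it checks.
    """
    days = [d.toordinal() for d in pd.DatetimeIndex(dates)]
    vals = list(values)
    n = len(vals)
    exceed = [
        (not (isinstance(v, float) and math.isnan(v))) and v > threshold for v in vals
    ]
    flags = np.zeros(n, dtype=int)
    for i in range(n):
        if not exceed[i]:
            continue
        lo = i
        while lo - 1 >= 0 and exceed[lo - 1] and days[lo] - days[lo - 1] == 1:
            lo -= 1
        hi = i
        while hi + 1 < n and exceed[hi + 1] and days[hi + 1] - days[hi] == 1:
            hi += 1
        if hi - lo + 1 >= min_run:
            flags[i] = 1
    return flags


def nws_chart_value(t_f: float, rh: float) -> float:
    """Published heat-index chart entry: the regression evaluated directly
    in Fahrenheit (no unit round trip) and rounded to a whole degree, the
    way the chart tabulates it."""
    T, R = float(t_f), float(rh)
    hi = (
        -42.379
        + 2.04901523 * T
        + 10.14333127 * R
        - 0.22475541 * T * R
        - 6.83783e-3 * T**2
        - 5.481717e-2 * R**2
        + 1.22874e-3 * T**2 * R
        + 8.5282e-4 * T * R**2
        - 1.99e-6 * T**2 * R**2
    )
    if R < 13 and 80 <= T <= 112:
        hi -= ((13 - R) / 4) * math.sqrt((17 - abs(T - 95)) / 17)
    elif R > 85 and 80 <= T <= 87:
        hi += ((R - 85) / 10) * ((87 - T) / 5)
    return round(hi)
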