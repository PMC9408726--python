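"""Relative humidity and apparent temperature (heat index) from daily data.

RH comes from the August-Roche-Magnus saturation vapour-pressure ratio;
the apparent temperature is the NWS heat index: the Rothfusz regression
with the standard low-humidity subtraction and high-humidity addition,
falling back to the Steadman simple formula in cool conditions.  Units are
degrees Celsius at the module boundary; the regression polynomial operates
in Fahrenheit internally.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

# August-Roche-Magnus constants (saturation vapour pressure over water)
MAGNUS_A = 17.625
MAGNUS_B = 243.04  # deg C


def c_to_f(t):
    return np.asarray(t, dtype=float) * 9.0 / 5.0 + 32.0


def f_to_c(t):
    return (np.asarray(t, dtype=float) - 32.0) * 5.0 / 9.0


def dewpoint_to_rh(t, td):
    """Relative humidity (%) from air temperature and dew point (deg C).

    RH = 100 * e(td) / e(t) with e(x) = exp(A*x / (B + x)).  A dew point
    above the air temperature is physically inconsistent but occurs in real
    station data; the result is clamped to 100% with a warning.  Missing
    inputs propagate to missing output.
    """
    t = np.asarray(t, dtype=float)
    td = np.asarray(td, dtype=float)
    rh = 100.0 * np.exp(MAGNUS_A * td / (MAGNUS_B + td) - MAGNUS_A * t / (MAGNUS_B + t))
    over = rh > 100.0
    if np.any(over):
        warnings.warn(
            f"dew point exceeds temperature on {int(np.sum(over))} record(s); RH clamped to 100%",
            stacklevel=2,
        )
        rh = np.where(over, 100.0, rh)
    return rh if rh.ndim else float(rh)


# Rothfusz regression coefficients (Fahrenheit)
_ROTHFUSZ = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


def heat_index(t_c, rh, rounded: bool = False):
    """NWS heat index (deg C) from air temperature (deg C) and RH (%).

    The Steadman simple formula averaged with the temperature is used when
    that average falls below 80 deg F; otherwise the Rothfusz regression
    applies, with the low-humidity adjustment (RH < 13%, 80-112 deg F)
    subtracted and the high-humidity adjustment (RH > 85%, 80-87 deg F)
    added.  ``rounded=True`` rounds to whole deg F before converting back,
    mimicking tabulated charts; the default keeps full precision.

    Raises ValueError when a non-missing RH lies outside [0, 100].
    """
    t_c = np.asarray(t_c, dtype=float)
    rh = np.asarray(rh, dtype=float)
    finite = ~np.isnan(rh)
    if np.any((rh[finite] < 0) | (rh[finite] > 100)):
        raise ValueError("relative humidity outside [0, 100]%")

    T = c_to_f(t_c)
    R = rh
    simple = 0.5 * (T + 61.0 + (T - 68.0) * 1.2 + R * 0.094)
    hi = (simple + T) / 2.0  # Steadman value averaged with the temperature

    c0, c1, c2, c3, c4, c5, c6, c7, c8 = _ROTHFUSZ
    full = (
        c0
        + c1 * T
        + c2 * R
        + c3 * T * R
        + c4 * T * T
        + c5 * R * R
        + c6 * T * T * R
        + c7 * T * R * R
        + c8 * T * T * R * R
    )
    with np.errstate(invalid="ignore"):
        low = (R < 13) & (T >= 80) & (T <= 112)
        high = (R > 85) & (T >= 80) & (T <= 87)
        full = np.where(
            low, full - ((13.0 - R) / 4.0) * np.sqrt((17.0 - np.abs(T - 95.0)) / 17.0), full
        )
        full = np.where(high, full + ((R - 85.0) / 10.0) * ((87.0 - T) / 5.0), full)
        hi = np.where(hi >= 80.0, full, hi)
    if rounded:
        hi = np.round(hi)
    out = f_to_c(hi)
    return out if out.ndim else float(out)


def derive_metrics(series: pd.DataFrame, rounded: bool = False) -> pd.DataFrame:
    """Add ``rh`` and ``at_max`` columns to a regional daily-weather frame.

    rh = dewpoint_to_rh(tmax, dewpoint); at_max = heat_index(tmax, rh).
    Rows missing tmax or dewpoint get missing derived values.
    """
    out = series.copy()
    if len(out) == 0:
        out["rh"] = pd.Series(dtype=float)
        out["at_max"] = pd.Series(dtype=float)
        return out
    out["rh"] = dewpoint_to_rh(out["tmax"].to_numpy(), out["dewpoint"].to_numpy())
    out["at_max"] = heat_index(out["tmax"].to_numpy(), out["rh"].to_numpy(), rounded=rounded)
    return out
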