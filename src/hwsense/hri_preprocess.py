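"""Small-count censoring and imputation for daily HRI series.

Surveillance products suppress days with fewer than five visits for
privacy; such days arrive marked censored and are imputed with a constant
(the reported median of 3 visits per day).  Both the cutoff and the
imputation value are configurable; the defaults follow the surveillance
convention.  Censoring is strict "< cutoff": a day exactly at the cutoff
is uncensored.
"""

from __future__ import annotations

import pandas as pd


def apply_censoring(counts: pd.Series, cutoff: int = 5) -> pd.DataFrame:
    """Mark days with count < cutoff as censored.

    Used by the synthetic generator to emulate the surveillance product.
    Returns a frame with ``count`` and ``censored`` columns on the input
    index; the counts themselves are untouched.
    """
    counts = counts.astype(int)
    if (counts < 0).any():
        raise ValueError("apply_censoring: negative counts")
    return pd.DataFrame({"count": counts, "censored": counts < cutoff}, index=counts.index)


def impute_censored(series: pd.DataFrame, impute_value: int = 3) -> tuple[pd.DataFrame, float]:
    """Replace every censored day's count with ``impute_value``.

    Uncensored days are untouched.  Returns the processed series and the
    censoring fraction (mean of the censored flags).
    """
    if impute_value < 0:
        raise ValueError("impute_censored: negative imputation value")
    if "censored" not in series.columns:
        raise KeyError("impute_censored: series lacks a 'censored' column")
    out = series.copy()
    out.loc[out["censored"], "count"] = impute_value
    fraction = float(series["censored"].mean()) if len(series) else 0.0
    return out, fraction


def censoring_fraction(series: pd.DataFrame) -> float:
    return float(series["censored"].mean()) if len(series) else 0.0
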