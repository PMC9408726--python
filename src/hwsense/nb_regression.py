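"""Negative-binomial regression of daily HRI counts on heat-wave flags.

For each definition the daily count is modelled as NB2 (log link, variance
mu + mu^2/theta) with a log-population offset:

    log E(count) = log(pop) + b0 + b_HW*HW + b_RH*RH + b_NWS*NWS_HW
                   + weekend + month factor + year factor

Relative humidity enters only when the heat metric is a plain temperature;
apparent-temperature definitions already fold humidity into the exposure,
so their models adjust for the NWS flag alone among the heat covariates.
The heat-wave coefficient exponentiates to the rate ratio; definitions are
ranked by AIC = 2k - 2 log L with k counting the mean-model coefficients
plus the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import AlignmentError, ConvergenceError, DegenerateDesignError
from .hwd_engine import HWDefinition

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Design:
    """Aligned design matrix, offset vector, and bookkeeping for one model."""

    X: pd.DataFrame
    offset: np.ndarray
    n_dropped: int


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    theta: float
    llf: float
    aic: float
    n: int
    n_dropped: int = 0
    converged: bool = True


@dataclass
class RateRatio:
    point: float
    lo: float
    hi: float


def build_design(
    hw_flags: pd.Series,
    weather: pd.DataFrame,
    nws_flags: pd.Series,
    population: float,
    include_rh: bool = True,
    month_reference: int = 5,
    weekend_days: tuple[int, ...] = (5, 6),
) -> Design:
    """Assemble the covariate matrix for one definition's model.

    ``weather`` is the regional daily frame (indexed or keyed by date) and
    must carry ``rh`` when ``include_rh``.  All series must share the same
    dates.  Columns: intercept, hw, [rh], nws_hw, weekend, month dummies
    (reference May), year dummies (reference first year).  Rows with any
    missing covariate are dropped; the count is recorded on the result.
    """
    dates = pd.DatetimeIndex(hw_flags.index)
    if weather.index.name != "date" and "date" in weather.columns:
        weather = weather.set_index("date")
    if not dates.equals(pd.DatetimeIndex(weather.index)) or not dates.equals(
        pd.DatetimeIndex(nws_flags.index)
    ):
        raise AlignmentError("build_design: flag, weather and NWS series are not on the same dates")
    if population <= 0:
        raise ValueError("population must be positive")

    X = pd.DataFrame(index=dates)
    X["const"] = 1.0
    X["hw"] = hw_flags.astype(float).to_numpy()
    if include_rh:
        X["rh"] = weather["rh"].to_numpy()
    X["nws_hw"] = nws_flags.astype(float).to_numpy()
    X["weekend"] = np.isin(dates.dayofweek, weekend_days).astype(float)
    for m in sorted(set(dates.month) - {month_reference}):
        X[f"month_{m}"] = (dates.month == m).astype(float)
    years = sorted(set(dates.year))
    for y in years[1:]:
        X[f"year_{y}"] = (dates.year == y).astype(float)

    keep = ~X.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    X = X.loc[keep]
    offset = np.full(len(X), np.log(population))
    return Design(X=X, offset=offset, n_dropped=n_dropped)


def fit_nb(design: Design | pd.DataFrame, offset=None, counts=None) -> ModelFit:
    """Maximum-likelihood NB2 fit with the given offset.

    Accepts either a :class:`Design` plus a count series, or raw
    ``(X, offset, counts)``.  Dispersion theta is estimated jointly by ML
    (statsmodels parameterises it as alpha = 1/theta).  Raises
    DegenerateDesignError for a constant non-intercept column and
    ConvergenceError (with the optimiser trace attached) when the
    likelihood cannot be maximised.
    """
    if isinstance(design, Design):
        X, off = design.X, design.offset
        n_dropped = design.n_dropped
    else:
        X, off = design, offset
        n_dropped = 0
    if counts is None:
        raise TypeError("fit_nb requires the count series via counts=")
    y = np.asarray(counts, dtype=float)
    if len(y) != len(X):
        raise AlignmentError(f"fit_nb: {len(X)} design rows but {len(y)} counts")
    if len(X) <= X.shape[1]:
        raise ValueError("fit_nb: fewer observations than coefficients")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("fit_nb: counts must be non-negative integers")
    for col in X.columns:
        if col != "const" and X[col].nunique() <= 1:
            raise DegenerateDesignError(
                f"design column {col!r} is constant; model is not identifiable", column=col
            )

    model = sm.NegativeBinomial(y, X, offset=np.asarray(off, dtype=float), loglike_method="nb2")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=500, method="bfgs", gtol=1e-8)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=200, method="newton", start_params=res.params)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "negative-binomial fit did not converge", trace=res.mle_retvals
        )

    params = pd.Series(res.params, index=list(X.columns) + ["alpha"])
    bse = pd.Series(res.bse, index=params.index)
    alpha = float(params["alpha"])
    k = len(params)  # mean-model coefficients + dispersion
    llf = float(res.llf)
    return ModelFit(
        params=params.drop("alpha"),
        bse=bse.drop("alpha"),
        theta=float(1.0 / alpha) if alpha > 0 else float("inf"),
        llf=llf,
        aic=2.0 * k - 2.0 * llf,
        n=len(y),
        n_dropped=n_dropped,
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def rate_ratio(fit: ModelFit, term: str = "hw") -> RateRatio:
    """RR = exp(beta) with a Wald 95% CI on the log scale."""
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fitted model")
    b = float(fit.params[term])
    se = float(fit.bse[term])
    return RateRatio(point=float(np.exp(b)), lo=float(np.exp(b - Z_95 * se)), hi=float(np.exp(b + Z_95 * se)))


def rank_definitions(
    fits: Mapping[str, "ModelFit | float"],
) -> tuple[list[tuple[str, float]], str]:
    """Order definitions by ascending AIC; ties break lexicographically by id.

    Accepts ModelFit objects or bare AIC values.  Returns the ordered
    (id, AIC) list and the optimal id.
    """
    if not fits:
        raise ValueError("rank_definitions: no fits")
    pairs = [
        (def_id, float(fit.aic) if isinstance(fit, ModelFit) else float(fit))
        for def_id, fit in fits.items()
    ]
    ordered = sorted(pairs, key=lambda p: (p[1], p[0]))
    return ordered, ordered[0][0]


def fit_all_definitions(
    weather: pd.DataFrame,
    flags: Mapping[str, pd.Series],
    nws_flags: pd.Series,
    counts: pd.Series,
    population: float,
    definitions: Mapping[str, HWDefinition],
) -> dict[str, ModelFit]:
    """Fit the per-definition model for one region.

    ``flags`` and ``definitions`` are keyed by definition id; RH is included
    exactly when the metric is a plain temperature.  Definitions whose
    design is degenerate (e.g. zero flagged days) or whose fit does not
    converge are skipped.
    """
    fits: dict[str, ModelFit] = {}
    for def_id, flag_series in flags.items():
        d = definitions[def_id]
        design = build_design(
            flag_series,
            weather,
            nws_flags,
            population,
            include_rh=(d.metric != "apparent_max"),
        )
        y = counts.loc[design.X.index]
        try:
            fits[def_id] = fit_nb(design, counts=y)
        except (DegenerateDesignError, ConvergenceError):
            continue
    return fits
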