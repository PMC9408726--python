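"""Synthetic weather, alerts and HRI counts with the structure the analysis assumes.

The generator emulates the study conditions: two physiographic regions,
five summer seasons (1 May-30 Sep) of station weather on top of a
120-year climatology for percentile thresholds, sparse NWS-style alert
intervals (~2.5% of study days), and daily heat-related-illness counts
drawn from the same NB2 regression the pipeline fits, with small counts
censored the way the surveillance product censors them.

Daily maximum temperature is a summer sinusoid plus AR(1) noise; a gentle
century trend plus a warm study-period offset put the recent seasons in
the upper tail of the long climatology, so that moderate-percentile
definitions flag a realistic 25-35% of study days.  Each stage draws from
its own stream spawned from the master seed by a fixed label, so adding a
stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import hri_preprocess, io_formats, weather_metrics
from .hwd_engine import HWDefinition, compute_thresholds, flag_days, standard_definitions
from .nb_regression import build_design

_STREAMS = {"weather": 0, "alerts": 1, "counts": 2}

DEFAULT_COUNTY_MAP = {
    "Carteret": "Coastal",
    "Craven": "Coastal",
    "New Hanover": "Coastal",
    "Guilford": "Piedmont",
    "Mecklenburg": "Piedmont",
    "Wake": "Piedmont",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Temperatures in deg C.  ``theta`` is the NB2 dispersion (variance
    mu + mu^2/theta); ``beta_*`` are the true log-scale coefficients of the
    generative count model.  ``study_offset_c`` is the mean warmth of the
    study seasons relative to the long climatology.
    """

    seed: int = 0
    regions: tuple[str, ...] = ("Coastal", "Piedmont")
    study_years: tuple[int, ...] = (2011, 2012, 2014, 2015, 2016)
    baseline_years: int = 120
    stations_per_region: int = 2
    # weather process
    peak_tmax_c: float = 33.0
    seasonal_amplitude_c: float = 5.0
    peak_doy: int = 200
    ar1: float = 0.65
    noise_sd: float = 2.5  # marginal sd of the AR(1) anomaly
    station_noise_sd: float = 0.5
    warming_per_century_c: float = 1.0
    study_offset_c: float = 2.1
    diurnal_range_mean: float = 10.0
    diurnal_range_sd: float = 1.5
    dewpoint_offset_mean: float = 8.0
    dewpoint_offset_sd: float = 2.5
    # count model
    true_definition_id: str = "HW_15"
    base_daily_rate: float = 4.2  # expected unflagged-day count before covariates
    beta_hw: float = float(np.log(2.75))
    beta_rh: float = 0.004
    beta_nws: float = 0.25
    beta_weekend: float = -0.05
    month_effects: tuple[tuple[int, float], ...] = ((6, 0.15), (7, 0.30), (8, 0.20), (9, 0.0))
    year_effects: tuple[tuple[int, float], ...] = ()
    theta: float = 5.0
    population: tuple[tuple[str, float], ...] = (("Coastal", 2_600_000.0), ("Piedmont", 5_100_000.0))
    censor_cutoff: int = 5
    # alerts
    alert_target_fraction: float = 0.025
    county_map: tuple[tuple[str, str], ...] = tuple(sorted(DEFAULT_COUNTY_MAP.items()))

    def __post_init__(self):
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError(f"AR(1) coefficient must lie in (-1, 1), got {self.ar1}")
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")
        if any(p <= 0 for _, p in self.population):
            raise ValueError("populations must be positive")

    @property
    def population_map(self) -> dict[str, float]:
        return dict(self.population)

    @property
    def region_map(self) -> dict[str, str]:
        return dict(self.county_map)

    @property
    def all_years(self) -> tuple[int, ...]:
        first = min(self.study_years)
        base = tuple(range(first - self.baseline_years, first))
        return base + tuple(sorted(self.study_years))


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[label],)))


def _seasonal(doy: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    return cfg.peak_tmax_c - cfg.seasonal_amplitude_c * (
        1.0 - np.cos(2.0 * np.pi * (doy - cfg.peak_doy) / 365.0)
    )


def simulate_weather(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Station-day weather for the full climatology plus study period.

    Regional daily tmax = seasonal sinusoid + year anomaly + AR(1) noise
    (independent across summers); stations add small iid offsets; tmin is
    tmax minus a positive diurnal range, tmean their midpoint, dew point
    tmax minus a positive offset.  Identical seed => identical output.
    """
    rng = _stream(config.seed, "weather") if rng is None else rng
    years = config.all_years
    first_year = years[0]
    study = set(config.study_years)
    dates = io_formats.summer_dates(years)
    doy = dates.dayofyear.to_numpy()
    year_arr = dates.year.to_numpy()
    n = len(dates)
    n_years = len(years)
    days_per_season = n // n_years  # 153

    anomaly = config.warming_per_century_c * (year_arr - first_year) / 100.0
    anomaly = anomaly + np.where(np.isin(year_arr, list(study)), config.study_offset_c, 0.0)
    base = _seasonal(doy, config) + anomaly

    innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1**2)
    frames = []
    burn = 30
    for region in config.regions:
        innov = rng.normal(0.0, innov_sd, size=(n_years, days_per_season + burn))
        ar = lfilter([1.0], [1.0, -config.ar1], innov, axis=1)[:, burn:]
        tmax_region = base + ar.ravel()
        for s in range(config.stations_per_region):
            tmax = tmax_region + rng.normal(0.0, config.station_noise_sd, n)
            diurnal = np.clip(
                rng.normal(config.diurnal_range_mean, config.diurnal_range_sd, n), 2.0, None
            )
            dew_off = np.clip(
                rng.normal(config.dewpoint_offset_mean, config.dewpoint_offset_sd, n), 0.5, None
            )
            frames.append(
                pd.DataFrame(
                    {
                        "date": dates,
                        "station_id": f"{region[:2].upper()}{s + 1:02d}",
                        "region": region,
                        "tmin": tmax - diurnal,
                        "tmax": tmax,
                        "tmean": tmax - diurnal / 2.0,
                        "dewpoint": tmax - dew_off,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["date", "station_id"], kind="stable").reset_index(drop=True)


def simulate_alerts(
    study_weather: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Alert intervals covering the hottest ~2.5% of study days per region.

    Days whose apparent-max exceeds the (1 - target) empirical quantile are
    grouped into maximal consecutive intervals; each interval is attributed
    to a random county of its region and typed by its peak apparent-max.
    """
    rng = _stream(config.seed, "alerts") if rng is None else rng
    counties_by_region: dict[str, list[str]] = {}
    for county, region in config.county_map:
        counties_by_region.setdefault(region, []).append(county)
    rows = []
    for region, sub in study_weather.groupby("region", sort=True):
        sub = sub.sort_values("date")
        at = sub["at_max"].to_numpy()
        dates = pd.DatetimeIndex(sub["date"])
        thr = np.quantile(at, 1.0 - config.alert_target_fraction)
        warn_thr = np.quantile(at, 1.0 - config.alert_target_fraction / 5.0)
        hot = at > thr
        if not hot.any():
            continue
        idx = np.flatnonzero(hot)
        breaks = np.flatnonzero(
            np.diff(dates[idx].values).astype("timedelta64[D]") != np.timedelta64(1, "D")
        )
        for chunk in np.split(idx, breaks + 1):
            product = (
                "excessive_heat_warning" if np.max(at[chunk]) > warn_thr else "advisory"
            )
            rows.append(
                {
                    "start_date": dates[chunk[0]],
                    "end_date": dates[chunk[-1]],
                    "county": rng.choice(counties_by_region[region]),
                    "product": product,
                }
            )
    return pd.DataFrame(rows, columns=["start_date", "end_date", "county", "product"])


def true_coefficients(columns, config: SyntheticConfig, population: float) -> pd.Series:
    """Generative coefficient vector aligned to a design-matrix column order.

    The intercept is log(base_daily_rate) - log(population), so the offset
    and intercept together put an unflagged, covariate-free day at the
    configured base count in every region.
    """
    months = dict(config.month_effects)
    years = dict(config.year_effects)
    named = {
        "const": log(config.base_daily_rate) - log(population),
        "hw": config.beta_hw,
        "rh": config.beta_rh,
        "nws_hw": config.beta_nws,
        "weekend": config.beta_weekend,
    }
    vals = []
    for col in columns:
        if col in named:
            vals.append(named[col])
        elif col.startswith("month_"):
            vals.append(months.get(int(col.split("_")[1]), 0.0))
        elif col.startswith("year_"):
            vals.append(years.get(int(col.split("_")[1]), 0.0))
        else:
            raise KeyError(f"no true coefficient for design column {col!r}")
    return pd.Series(vals, index=list(columns))


def simulate_counts(
    X: pd.DataFrame,
    beta: pd.Series,
    theta: float,
    population: float,
    rng: np.random.Generator,
) -> pd.Series:
    """NB2 counts with log mu = X beta + log(population) (gamma-Poisson mixture)."""
    mu = np.exp(X.to_numpy() @ beta.to_numpy() + log(population))
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return pd.Series(rng.poisson(lam).astype(int), index=X.index, name="count")


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, in memory."""

    config: SyntheticConfig
    station_weather: pd.DataFrame      # all years, station scale
    climatology: pd.DataFrame          # regional daily metrics, all years
    study_weather: pd.DataFrame        # regional daily metrics, study years only
    region_map: dict[str, str]
    alerts: pd.DataFrame
    nws_flags: dict[str, pd.Series]
    thresholds: dict[tuple[str, str], float]
    true_flags: dict[str, pd.Series]
    raw_counts: dict[str, pd.Series]
    hri: pd.DataFrame                  # delivered product: censored counts masked to 0

    def write(self, directory) -> dict[str, Path]:
        """Emit the CSVs the readers consume; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "weather": directory / "weather.csv",
            "hri": directory / "hri.csv",
            "alerts": directory / "alerts.csv",
            "region_map": directory / "region_map.csv",
        }
        w = self.station_weather.copy()
        w["date"] = w["date"].dt.strftime("%Y-%m-%d")
        w.to_csv(paths["weather"], index=False, float_format="%.4f")
        h = self.hri.copy()
        h["date"] = h["date"].dt.strftime("%Y-%m-%d")
        h.to_csv(paths["hri"], index=False)
        a = self.alerts.copy()
        if len(a):
            a["start_date"] = a["start_date"].dt.strftime("%Y-%m-%d")
            a["end_date"] = a["end_date"].dt.strftime("%Y-%m-%d")
        a.to_csv(paths["alerts"], index=False)
        pd.DataFrame(
            sorted(self.region_map.items()), columns=["county", "region"]
        ).to_csv(paths["region_map"], index=False)
        return paths


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Run all three generators coherently and censor the counts.

    Counts are generated from the configured true definition's flags via
    the same design builder the fits use; days falling below the censor
    cutoff are delivered with count 0 and ``censored=True``, mirroring the
    masked surveillance product.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    definitions = {d.id: d for d in standard_definitions()}
    true_def = definitions[config.true_definition_id]

    station = simulate_weather(config)
    climatology = weather_metrics.derive_metrics(io_formats.aggregate_to_region(station))
    study_mask = climatology["date"].dt.year.isin(config.study_years)
    study = climatology.loc[study_mask].reset_index(drop=True)

    alerts = simulate_alerts(study, config)
    window = io_formats.summer_dates(config.study_years)
    nws_flags = io_formats.expand_alerts(alerts, config.region_map, window)

    thresholds = compute_thresholds(climatology, [true_def])
    rng_counts = _stream(config.seed, "counts")
    true_flags: dict[str, pd.Series] = {}
    raw_counts: dict[str, pd.Series] = {}
    hri_rows = []
    for region in config.regions:
        sub = study[study["region"] == region].sort_values("date")
        from .hwd_engine import METRIC_COLUMNS

        flags = flag_days(
            sub["date"], sub[METRIC_COLUMNS[true_def.metric]], true_def,
            thresholds[(region, true_def.id)],
        )
        true_flags[region] = flags
        design = build_design(
            flags,
            sub,
            nws_flags[region],
            config.population_map[region],
            include_rh=(true_def.metric != "apparent_max"),
        )
        beta = true_coefficients(design.X.columns, config, config.population_map[region])
        counts = simulate_counts(
            design.X, beta, config.theta, config.population_map[region], rng_counts
        )
        raw_counts[region] = counts
        censored = hri_preprocess.apply_censoring(counts, cutoff=config.censor_cutoff)
        delivered = censored.copy()
        delivered.loc[delivered["censored"], "count"] = 0
        for date, row in delivered.iterrows():
            hri_rows.append(
                {
                    "date": date,
                    "region": region,
                    "count": int(row["count"]),
                    "censored": bool(row["censored"]),
                }
            )
    hri = pd.DataFrame(hri_rows)
    return SyntheticDataset(
        config=config,
        station_weather=station,
        climatology=climatology,
        study_weather=study,
        region_map=config.region_map,
        alerts=alerts,
        nws_flags=nws_flags,
        thresholds=thresholds,
        true_flags=true_flags,
        raw_counts=raw_counts,
        hri=hri,
    )
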