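# Methods

## The definition grammar

A heat-wave definition (HWD) is a tuple *(metric, duration, threshold
type, intensity)*. The standard set of 28 definitions spans daily mean
(HW_01–08), maximum (HW_09–16) and minimum (HW_18–25) temperature over a
(2+/3+ consecutive days) × (99/98/95/90th percentile) grid, one absolute
single-day rule (HW_17: max temperature > 35 °C), and three single-day
apparent-temperature percentile rules (HW_26–28 at the 95/90/85th
percentiles). HW_26–28 are encoded as *relative* (percentile)
definitions: their thresholds are climatological quantiles that differ by
region, even though single-day rules are sometimes grouped with the
absolute ones.

**Exceedance is strict** (`value > threshold`): a day exactly at the
threshold is not an exceedance. This matches how the cutoffs are stated
(">90th percentile", ">35 °C"); with continuous temperature data ties are
measure-zero anyway, but the convention matters for the absolute rule.

**Run detection.** For a *k*+ definition a day is flagged iff it belongs
to a maximal run of consecutive exceedance days of length ≥ *k*. Runs
break at missing values (a day of unknown temperature never contributes
exposure) and wherever consecutive dates in the window are more than one
calendar day apart — in particular across the gap between 30 September
and the following 1 May, since physiological heat exposure cannot
accumulate over a winter. 31 May → 1 June is contiguous and continues a
run.

**Thresholds.** Percentile thresholds are computed from all summer days
of the configured climatology years with linear interpolation between
order statistics (position *h = (n−1)·p/100 + 1*, the numpy default);
the interpolation method is configurable. Missing values are dropped; an
empty baseline is an error, not a silent NaN.

## Heat metrics

Relative humidity uses the August–Roche–Magnus form
RH = 100·e(td)/e(t), e(x) = exp(17.625·x/(243.04 + x)). Dew points above
the air temperature (which occur in real station records) clamp RH to
100% with a warning instead of erroring. The apparent temperature is the
NWS heat index: below an 80 °F screening value (the Steadman simple
formula averaged with the temperature) the simple value is returned;
above it, the Rothfusz regression applies with the standard low-humidity
subtraction (RH < 13%, 80–112 °F) and high-humidity addition (RH > 85%,
80–87 °F). The module works in °C; the polynomial runs in °F internally.
The result is **not** rounded to whole degrees by default — thresholds
are carried at 0.01 °C precision — but a `rounded` flag reproduces the
tabulated-chart convention. Station values are aggregated to regions by
an unweighted mean over the stations reporting each field that day; the
aggregation is deliberately the simplest defensible choice and is
isolated behind one function.

## Count model

Daily HRI counts are censored below 5 visits by the surveillance
provider; censored days are imputed with the constant 3 (the reported
median of suppressed days) before modelling. Both constants are
configurable. The per-definition model is an NB2 GLM (log link, variance
μ + μ²/θ, θ estimated by maximum likelihood) with offset log(2010
regional population): covariates are the definition's flag, relative
humidity (omitted for apparent-temperature metrics, which already embed
humidity), the NWS alert flag, a weekend indicator (Sat/Sun), month
factor (reference May) and year factor (reference first study year).
Rows with any missing covariate are dropped list-wise and the count
reported. Fitting goes through `statsmodels`' discrete `NegativeBinomial`
(BFGS with a Newton polish on non-convergence); the tests verify exact
agreement (coefficients, θ, log-likelihood, AIC) with `MASS::glm.nb` in
R, the standard toolchain for this model. AIC is 2k − 2·log L with k
counting the mean-model coefficients plus the dispersion; ranking is by
ascending AIC with lexicographic tie-break on definition id. Rate-ratio
intervals are Wald on the log scale (the CI method is otherwise
unstated in practice); a degenerate design (e.g. a definition that flags
zero days) raises a named error and is excluded from the ranking rather
than silently fitted.

## Alert comparison

Study flags vs NWS alert days form a 2×2 table per region (a = both,
b = study only, c = NWS only, d = neither). The McNemar statistic uses
only the discordant cells; the continuity-corrected form
χ² = (max(|b−c|−1, 0))² / (b+c) is the default because the reported
worked-example statistics (158.15 and 219.04) are reproduced *exactly*
by the corrected formula on integer-consistent tables — from marginals
190/26 (n = 704) and 241/18 (n = 719) the overlaps must be 24 and 17,
giving discordant cells 166/2 and 224/1 — whereas no integer table
reproduces them uncorrected. The |b−c|−1 numerator is clamped at zero so
b = c yields χ² = 0 rather than a spurious positive value. NWS intervals
are expanded to daily regional flags inclusively on both endpoints
(advisories are published as whole days); advisories and excessive-heat
warnings both count, and a region-day is flagged if any county mapped to
the region is covered.

## Synthetic generator

The generator emulates the restricted study record so every stage is
testable offline; its defaults are the study conditions, not tuning
knobs.

* **Weather.** Two regions × (120 climatology years + 5 study summers,
  2011–2016 without 2013), 2 stations per region, days 1 May–30 Sep.
  Regional daily tmax = seasonal sinusoid (peak 33 °C around day 200,
  amplitude 5 °C) + year anomaly + AR(1) noise (φ = 0.65, marginal
  sd 2.5 °C, independent across summers); stations add iid noise
  (sd 0.5 °C). tmin subtracts a positive diurnal range (mean 10 °C),
  tmean is the midpoint, dew point sits a positive offset (mean 8 °C)
  below tmax. The year anomaly is a 1 °C/century trend plus a
  2.1 °C study-period offset; the offset was calibrated once so that
  2+-day / 90th-percentile definitions flag ~25–35% of study days (the
  regime the analysis operates in) and then frozen. The generator's
  humid-hot profile makes apparent-temperature values run high (~50 °C
  peaks); only their ranks matter for percentile definitions.
* **Alerts.** Days whose regional apparent-max exceeds the empirical
  (1 − 0.025) quantile of the study period are grouped into consecutive
  intervals, attributed to a random county of the region, and typed
  advisory vs excessive-heat warning by peak intensity — matching the
  ~2.5% alert-day sparsity of real heat products.
* **Counts.** Drawn from the same NB2 design the fits use (generative
  twin): log μ = Xβ + log(pop) with true definition HW_15,
  β_HW = ln 2.75, θ = 5, small humidity/alert/weekend/month effects, and
  a per-region intercept of log(4.2/pop) so an unflagged covariate-free
  day expects 4.2 visits. That base rate was calibrated once so ~29% of
  raw days fall below the censoring cutoff of 5, matching the reported
  censoring regime; the delivered product masks censored counts to 0
  with a flag, and the pipeline imputes 3.
* **Seeding.** Each stage (weather / alerts / counts) draws from its own
  `SeedSequence` child of the master seed, so adding a stage never
  perturbs another stage's stream; identical seeds give byte-identical
  CSVs.

What the generator does *not* emulate: spatial station networks and
area-weighted aggregation, humidity–temperature covariance beyond a
noisy offset, alert forecasting lead time, reporting-day-of-week
artefacts in counts, and any real climatology. Passing tests therefore
demonstrate the pipeline's statistical correctness and internal
consistency under known truth — not agreement with the real North
Carolina record, whose thresholds and AIC values require the restricted
1895–2016 weather and surveillance data.

## Problem sizes and numerics

The test suite and acceptance script use the study-scale defaults
(n = 765 study days per region, 28 definitions × 2 regions = 56 NB fits
per replicate; 25 pipeline replicates; 100 count replicates for
coefficient coverage; 1000 random series for the flagging oracle), which
run in about two minutes on one CPU. Flagging correctness is checked
against a naive day-by-day window-enumeration oracle; NB fits against
`MASS::glm.nb`; the McNemar implementation against `statsmodels`'
(unclamped) version where both are defined. Degenerate inputs (empty
baselines, all-censored series, constant design columns, b + c = 0
tables, zero-variance weather) raise informative errors or produce the
documented limiting values rather than NaNs.

## Known limitations

* Station aggregation is an unweighted mean; the real analysis may have
  used areal weighting (unstated), so regional metrics can differ.
* The Wald CI and May/first-year reference levels are conventional
  choices; none are stated by the source analyses.
* The end-to-end recovery property is stochastic: with highly correlated
  definitions (HW_15/HW_16/HW_07 share most of their flagged days) the
  ranking may select a near-duplicate of the truth; the acceptance
  property counts a Jaccard ≥ 0.8 neighbour as success for that reason.
* Imputing censored days at the constant 3 biases coefficients toward
  null when the true censored-day mean differs from 3; the pipeline
  reports the censoring fraction so users can judge exposure.
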