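import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_flags
from hwsense import hwd_engine as he
from hwsense.exceptions import AlignmentError


def _series(values, start="2011-07-01"):
    return pd.date_range(start, periods=len(values)), np.asarray(values, dtype=float)


class TestStandardDefinitions:
    def test_exactly_28_with_expected_ids(self):
        defs = he.standard_definitions()
        assert [d.id for d in defs] == [f"HW_{i:02d}" for i in range(1, 29)]

    def test_known_rows(self):
        by_id = {d.id: d for d in he.standard_definitions()}
        assert by_id["HW_15"] == he.HWDefinition("HW_15", "max", 2, "relative", 90.0)
        assert by_id["HW_17"] == he.HWDefinition("HW_17", "max", 1, "absolute", 35.0)
        assert by_id["HW_01"].metric == "mean" and by_id["HW_01"].intensity == 99.0
        assert by_id["HW_26"] == he.HWDefinition("HW_26", "apparent_max", 1, "relative", 95.0)
        assert by_id["HW_28"].intensity == 85.0

    def test_single_day_only_for_absolute_and_apparent(self):
        for d in he.standard_definitions():
            if d.min_run == 1:
                assert d.id in {"HW_17", "HW_26", "HW_27", "HW_28"}
            else:
                assert d.min_run in (2, 3) and d.threshold_type == "relative"

    def test_percentiles_in_listed_set(self):
        for d in he.standard_definitions():
            if d.threshold_type == "relative":
                assert d.intensity in {99.0, 98.0, 95.0, 90.0, 85.0}


class TestComputeThreshold:
    def test_constant_series(self):
        for p in (50, 90, 99):
            assert he.compute_threshold([30.0] * 10, p) == 30.0

    def test_linear_interpolation_order_statistics(self):
        # position h = (n-1)*90/100 + 1 = 90.1 for values 1..100
        assert he.compute_threshold(np.arange(1.0, 101.0), 90) == pytest.approx(90.1)

    def test_median_of_five(self):
        assert he.compute_threshold([1, 2, 3, 4, 5], 50) == 3.0

    def test_missing_dropped_then_empty_errors(self):
        assert he.compute_threshold([np.nan, 10.0], 50) == 10.0
        with pytest.raises(ValueError):
            he.compute_threshold([np.nan, np.nan], 50)

    def test_threshold_nondecreasing_in_percentile(self, quick_dataset):
        clim = quick_dataset.climatology
        defs = he.standard_definitions()
        thr = he.compute_thresholds(clim, defs)
        for region in quick_dataset.config.regions:
            for metric, ids in (("max", ["HW_15", "HW_13", "HW_11", "HW_09"]),
                                ("mean", ["HW_07", "HW_05", "HW_03", "HW_01"])):
                vals = [thr[(region, i)] for i in ids]  # 90 -> 95 -> 98 -> 99
                assert vals == sorted(vals)


class TestFlagDays:
    def test_run_length_rule(self):
        dates, vals = _series([30, 33, 33, 30, 33])
        d2 = he.HWDefinition("X", "max", 2, "absolute", 32.0)
        flags = he.flag_days(dates, vals, d2, 32.0)
        assert list(flags) == [0, 1, 1, 0, 0]  # trailing singleton not flagged

    def test_three_day_rule_all_zero(self):
        dates, vals = _series([30, 33, 33, 30, 33])
        d3 = he.HWDefinition("X", "max", 3, "absolute", 32.0)
        assert he.flag_days(dates, vals, d3, 32.0).sum() == 0

    def test_strict_inequality_at_threshold(self):
        dates, vals = _series([35.0, 35.0001])
        d1 = he.HWDefinition("HW_17", "max", 1, "absolute", 35.0)
        assert list(he.flag_days(dates, vals, d1, 35.0)) == [0, 1]

    def test_missing_values_break_runs(self):
        dates, _ = _series([0] * 5)
        vals = np.array([33.0, np.nan, 33.0, 33.0, 33.0])
        d3 = he.HWDefinition("X", "max", 3, "absolute", 32.0)
        assert list(he.flag_days(dates, vals, d3, 32.0)) == [0, 0, 1, 1, 1]

    def test_runs_do_not_span_seasons(self):
        dates = pd.DatetimeIndex(
            ["2011-09-29", "2011-09-30", "2012-05-01", "2012-05-02"]
        )
        vals = np.array([33.0] * 4)
        d3 = he.HWDefinition("X", "max", 3, "absolute", 32.0)
        # two hot days either side of the winter gap never make a 3-day run
        assert he.flag_days(dates, vals, d3, 32.0).sum() == 0
        d2 = he.HWDefinition("X", "max", 2, "absolute", 32.0)
        assert list(he.flag_days(dates, vals, d2, 32.0)) == [1, 1, 1, 1]

    def test_runs_continue_across_month_boundary(self):
        dates = pd.DatetimeIndex(["2011-05-31", "2011-06-01", "2011-06-02"])
        vals = np.array([33.0, 33.0, 33.0])
        d3 = he.HWDefinition("X", "max", 3, "absolute", 32.0)
        assert he.flag_days(dates, vals, d3, 32.0).sum() == 3

    def test_length_mismatch_is_error(self):
        dates, _ = _series([0, 0, 0])
        with pytest.raises(AlignmentError):
            he.flag_days(dates, [1.0, 2.0], he.HWDefinition("X", "max", 1, "absolute", 0), 0.0)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 61))
            dates = pd.date_range("2011-05-01", periods=n)
            if n > 3 and rng.random() < 0.5:  # inject an off-season gap
                cut = int(rng.integers(1, n))
                dates = dates[:cut].append(
                    pd.date_range("2012-05-01", periods=n - cut)
                )
            vals = rng.normal(31, 3, n)
            vals[rng.random(n) < 0.1] = np.nan
            thr = float(rng.normal(31, 2))
            for k in (1, 2, 3):
                d = he.HWDefinition("X", "max", k, "absolute", thr)
                got = he.flag_days(dates, vals, d, thr).to_numpy()
                expect = brute_force_flags(dates, vals, k, thr)
                np.testing.assert_array_equal(got, expect)


class TestFlagAll:
    def test_subset_and_monotonicity_properties(self, quick_dataset):
        ds = quick_dataset
        defs = he.standard_definitions()
        thr = he.compute_thresholds(ds.climatology, defs)
        study = ds.study_weather
        flags, counts = he.flag_all(study, defs, thr)
        counts = counts.set_index(["region", "definition_id"])["hw_days"]
        for region in ds.config.regions:
            # 3+ runs are a subset of 2+ runs, pointwise
            assert (flags[(region, "HW_16")] <= flags[(region, "HW_15")]).all()
            assert (flags[(region, "HW_08")] <= flags[(region, "HW_07")]).all()
            # counts shrink as the percentile rises at fixed metric/duration
            for ids in (["HW_15", "HW_13", "HW_11", "HW_09"], ["HW_07", "HW_05", "HW_03", "HW_01"]):
                series = [counts[(region, i)] for i in ids]
                assert series == sorted(series, reverse=True)
            # higher percentile flags are a pointwise subset at fixed metric/duration
            assert (flags[(region, "HW_09")] <= flags[(region, "HW_15")]).all()

    def test_count_equals_pointwise_sum(self, quick_dataset):
        ds = quick_dataset
        defs = he.standard_definitions()
        thr = he.compute_thresholds(ds.climatology, defs)
        flags, counts = he.flag_all(ds.study_weather, defs, thr)
        for row in counts.itertuples():
            assert row.hw_days == int(flags[(row.region, row.definition_id)].sum())

    def test_all_cold_series_yields_zero_counts(self):
        dates = pd.date_range("2011-05-01", "2011-09-30")
        weather = pd.DataFrame(
            {"region": "C", "date": dates, "tmean": 10.0, "tmax": 15.0, "tmin": 5.0,
             "at_max": 14.0}
        )
        defs = he.standard_definitions()
        clim = weather.assign(tmax=weather.tmax + np.linspace(0, 5, len(dates)))
        thr = he.compute_thresholds(clim.assign(tmean=clim.tmean, tmin=clim.tmin, at_max=clim.at_max), defs)
        _, counts = he.flag_all(weather, defs, thr)
        # every threshold sits at/above the cold series (absolute 35 C included)
        assert (counts["hw_days"] == 0).all()

    def test_unresolved_threshold_names_definition(self, quick_dataset):
        defs = he.standard_definitions()
        thr = he.compute_thresholds(quick_dataset.climatology, defs[:-1])
        with pytest.raises(KeyError, match="HW_28"):
            he.flag_all(quick_dataset.study_weather, defs, thr)
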