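"""Rolling baseline, anomaly labels, exposure/season/weekend classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anomviol import (
    AnomalyParams,
    classify_exposure,
    classify_panel,
    classify_rainfall,
    classify_temperature,
    rolling_baseline,
    season_of,
    summarize_anomalies,
    weekend_flag,
)

from conftest import make_classified_frame

PARAMS = AnomalyParams()


def naive_baseline(values, window=30):
    """Independent per-day recomputation: trailing window, sample SD."""
    values = np.asarray(values, dtype=float)
    mean = np.full(len(values), np.nan)
    sd = np.full(len(values), np.nan)
    for t in range(window, len(values)):
        chunk = values[t - window:t]
        mean[t] = chunk.mean()
        sd[t] = chunk.std(ddof=1)
    return mean, sd


class TestRollingBaseline:
    def test_constant_series(self):
        out = rolling_baseline(np.full(40, 7.5))
        complete = out[out["complete"]]
        assert len(complete) == 10
        assert (complete["baseline_mean"] == 7.5).all()
        assert (complete["baseline_sd"] == 0).all()

    def test_alternating_series_hand_value(self):
        """30 days alternating 10, 12 → day-31 mean 11, sample SD √(30/29)."""
        series = [10, 12] * 15 + [11]
        out = rolling_baseline(series)
        assert out.loc[30, "baseline_mean"] == pytest.approx(11.0, abs=1e-12)
        assert out.loc[30, "baseline_sd"] == pytest.approx(math.sqrt(30 / 29), abs=1e-12)
        assert not out.loc[29, "complete"]

    def test_incomplete_prefix_has_window_days(self):
        out = rolling_baseline(np.arange(100, dtype=float))
        assert (~out["complete"]).sum() == PARAMS.window
        assert list(out.index[~out["complete"]]) == list(range(PARAMS.window))

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=1000)
        out = rolling_baseline(values)
        mean, sd = naive_baseline(values)
        np.testing.assert_allclose(out["baseline_mean"], mean, atol=1e-9)
        np.testing.assert_allclose(out["baseline_sd"], sd, atol=1e-9)

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="shorter than"):
            rolling_baseline(np.zeros(30))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_future_values_cannot_change_a_days_baseline(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=60)
        t = int(rng.integers(31, 59))
        out_before = rolling_baseline(values)
        shuffled = values.copy()
        rng.shuffle(shuffled[t:])
        out_after = rolling_baseline(shuffled)
        assert out_after.loc[t, "baseline_mean"] == out_before.loc[t, "baseline_mean"]
        assert out_after.loc[t, "baseline_sd"] == out_before.loc[t, "baseline_sd"]


class TestClassifyTemperature:
    def test_value_at_baseline_mean_is_none(self):
        series = [10, 12] * 15 + [11]
        out = rolling_baseline(series)
        labels = classify_temperature(series, out)
        assert labels[30] == "none"

    def test_derived_upward_example(self):
        """Baseline mean 11, SD 1.0171; 13.6 departs z ≈ 2.56 > 2 → upward."""
        series = [10, 12] * 15 + [13.6]
        labels = classify_temperature(series, rolling_baseline(series))
        assert labels[30] == "upward"

    def test_zero_sd_window_yields_none(self):
        series = [5.0] * 30 + [9.0]
        labels = classify_temperature(series, rolling_baseline(series))
        assert labels[30] == "none"

    def test_warmup_is_unclassified(self):
        series = np.arange(40, dtype=float)
        labels = classify_temperature(series, rolling_baseline(series))
        assert (labels[:30] == "unclassified").all()
        assert set(labels) <= {"upward", "downward", "none", "unclassified"}

    @given(st.floats(0.1, 100), st.floats(-50, 50), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(10, 3, size=80)
        base = classify_temperature(values, rolling_baseline(values))
        scaled = a * values + b
        transformed = classify_temperature(scaled, rolling_baseline(scaled))
        assert (base == transformed).all()


class TestClassifyRainfall:
    def test_rain_after_all_dry_window_is_upward(self):
        series = [0.0] * 30 + [10.0]
        labels = classify_rainfall(series, rolling_baseline(series))
        assert labels[30] == "upward"

    def test_always_dry_is_none(self):
        series = np.zeros(60)
        labels = classify_rainfall(series, rolling_baseline(series))
        assert (labels[30:] == "none").all()

    def test_single_spike_in_light_rain_flagged_exactly(self):
        rng = np.random.default_rng(5)
        series = np.where(rng.random(40) < 0.4, rng.gamma(1.0, 2.0, 40), 0.0)
        series[35] = 25.0
        labels = classify_rainfall(series, rolling_baseline(series))
        mean, sd = naive_baseline(series)
        expected = {
            t for t in range(30, 40)
            if series[t] > 0 and series[t] > mean[t] + 2 * sd[t]
        }
        assert 35 in expected
        assert {t for t in range(40) if labels[t] == "upward"} == expected

    def test_negative_rainfall_rejected(self):
        series = np.zeros(40)
        series[5] = -1.0
        with pytest.raises(ValueError, match="negative"):
            classify_rainfall(series, rolling_baseline(np.zeros(40)))

    @given(st.floats(0.1, 50), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, a, seed):
        rng = np.random.default_rng(seed)
        values = np.where(rng.random(80) < 0.3, rng.gamma(0.6, 9.0, 80), 0.0)
        base = classify_rainfall(values, rolling_baseline(values))
        scaled = classify_rainfall(a * values, rolling_baseline(a * values))
        assert (base == scaled).all()


class TestExposureSeasonWeekend:
    def test_constant_series_all_medium(self):
        assert (classify_exposure(np.full(50, 3.0)) == "medium").all()

    def test_exact_one_sd_is_medium(self):
        # values {1,2,3}: mean 2, sample SD 1; both extremes sit exactly on
        # the band edge and the strict rule keeps them medium
        assert list(classify_exposure(np.array([1.0, 2.0, 3.0]))) == ["medium"] * 3

    def test_gaussian_tail_shares(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=200_000)
        labels = classify_exposure(values)
        for side in ("low", "high"):
            share = (labels == side).mean()
            assert abs(share - 0.1587) < 3 * math.sqrt(0.1587 * (1 - 0.1587) / len(values))

    @pytest.mark.parametrize("date,expected", [
        ("2013-01-15", "summer"), ("2013-12-01", "summer"),
        ("2013-07-01", "winter"), ("2013-04-10", "shoulder"),
    ])
    def test_season_of(self, date, expected):
        assert season_of([pd.Timestamp(date)])[0] == expected

    def test_weekend_flag(self):
        assert weekend_flag([pd.Timestamp("2013-01-05")])[0]  # Saturday
        assert weekend_flag([pd.Timestamp("2013-01-06")])[0]  # Sunday
        assert not weekend_flag([pd.Timestamp("2013-01-07")])[0]  # Monday
        weeks = pd.date_range("2013-01-07", periods=28, freq="D")
        assert weekend_flag(weeks).mean() == pytest.approx(2 / 7)


class TestSummarize:
    def test_no_anomalies(self):
        panel = make_classified_frame(100)
        panel["temp_baseline_mean"] = 15.0
        panel["rain_baseline_mean"] = 0.0
        out = summarize_anomalies(panel)
        assert (out["n_days"] == 0).all()
        assert (out["share_pct"] == 0.0).all()
        assert out["anomaly_mean"].isna().all()

    def test_single_injected_spike(self):
        n = 60
        temps = np.full(n, 15.0) + np.sin(np.arange(n))  # non-degenerate window
        temps[45] = 40.0
        panel = make_classified_frame(n, apparent_temperature_mean=temps)
        classified = classify_panel(panel.drop(columns=["temp_anomaly", "rain_anomaly",
                                                        "baseline_complete", "temp_z"]))
        out = summarize_anomalies(classified)
        row = out[(out["variable"] == "temperature") & (out["direction"] == "upward")].iloc[0]
        assert row["n_days"] == 1
        assert row["anomaly_mean"] == pytest.approx(40.0)
        assert row["share_pct"] == pytest.approx(100 / n)

    def test_share_uses_full_calendar_denominator(self, kha_run):
        panel = next(iter(kha_run.panels.values()))
        out = summarize_anomalies(panel)
        for _, row in out.iterrows():
            assert row["share_pct"] == pytest.approx(100 * row["n_days"] / len(panel))


class TestNullExceedanceRate:
    def test_estimated_baseline_exceedance_exceeds_fixed_gaussian_tail(self):
        """On i.i.d. Gaussian series the upward share matches an independent
        naive recomputation and is heavier than the fixed-threshold 2.28%
        tail, because the baseline mean and SD are estimated from 30 days."""
        rng = np.random.default_rng(3)
        impl_shares, naive_shares = [], []
        for _ in range(60):
            values = rng.normal(size=400)
            labels = classify_temperature(values, rolling_baseline(values))
            impl_shares.append((labels == "upward").sum() / (400 - 30))
            mean, sd = naive_baseline(values)
            flags = [values[t] > mean[t] + 2 * sd[t] for t in range(30, 400)]
            naive_shares.append(np.mean(flags))
        assert np.mean(impl_shares) == pytest.approx(np.mean(naive_shares), abs=1e-12)
        se = np.std(impl_shares, ddof=1) / math.sqrt(len(impl_shares))
        assert np.mean(impl_shares) - 3 * se > 0.0228


class TestClassifyPanelInvariants:
    def test_label_totality_and_exclusivity(self, kha_run):
        panel = next(iter(kha_run.panels.values()))
        assert panel["temp_anomaly"].isin(["upward", "downward", "none", "unclassified"]).all()
        assert (panel["temp_anomaly"] == "unclassified").sum() == PARAMS.window
        assert ((panel["temp_anomaly"] == "unclassified") == ~panel["baseline_complete"]).all()
        assert panel["exposure"].isin(["low", "medium", "high"]).all()

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AnomalyParams(window=1)
        with pytest.raises(ValueError):
            AnomalyParams(threshold_sd=0)
        with pytest.raises(ValueError):
            AnomalyParams(summer_months=frozenset({1}), winter_months=frozenset({1, 7}))
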