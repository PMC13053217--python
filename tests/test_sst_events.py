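import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kelpshift.sst_events import (
    DailySSTSeries,
    SeparationError,
    annual_event_indicator,
    annual_means,
    anomalies_and_correlation,
    days_above,
    detect_events,
    event_odds_trend,
    mann_kendall,
    read_daily_series,
    sen_slope,
    trend_rate,
    write_daily_series,
)


def flat_series(start="2000-01-01", days=365, value=15.0):
    dates = pd.date_range(start, periods=days, freq="D")
    return DailySSTSeries(dates=dates, sst=np.full(days, value))


def series_from(values, start="2000-06-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySSTSeries(dates=dates, sst=np.asarray(values, dtype=float))


class TestDailySSTSeries:
    def test_duplicate_dates_rejected(self):
        dates = pd.DatetimeIndex(["2000-01-01", "2000-01-01"])
        with pytest.raises(ValueError, match="duplicate"):
            DailySSTSeries(dates=dates, sst=np.array([1.0, 2.0]))

    def test_gap_years_flagged(self):
        dates = pd.DatetimeIndex(["2018-07-01", "2021-07-01"])
        s = DailySSTSeries(dates=dates, sst=np.array([15.0, 15.0]))
        assert s.gap_years() == [2019, 2020]

    def test_round_trip(self, tmp_path):
        s = flat_series(days=10)
        p = tmp_path / "sst.csv"
        write_daily_series(s, p)
        back = read_daily_series(p)
        assert (back.dates == s.dates).all()
        assert np.allclose(back.sst, s.sst)


class TestDaysAbove:
    def test_all_below_threshold(self):
        s = flat_series(days=730, value=17.9)
        counts = days_above(s, 18.0)
        assert (counts.dropna() == 0).all()

    def test_constant_20_summer_window(self):
        s = flat_series(start="2001-01-01", days=365, value=20.0)
        counts = days_above(s, 20.0, season="summer")
        assert counts.loc[2001] == 92  # Jun(30)+Jul(31)+Aug(31)

    def test_injected_days_counted_exactly(self):
        s = flat_series(start="2002-01-01", days=365, value=16.0)
        sst = s.sst.copy()
        idx = s.dates.get_loc(pd.Timestamp("2002-07-01"))
        sst[idx : idx + 10] = 18.5
        s2 = DailySSTSeries(dates=s.dates, sst=sst)
        assert days_above(s2, 18.0).loc[2002] == 10

    def test_missing_year_is_nan_not_zero(self):
        dates = pd.DatetimeIndex(["2000-07-01", "2002-07-01"])
        s = DailySSTSeries(dates=dates, sst=np.array([19.0, 19.0]))
        counts = days_above(s, 18.0)
        assert np.isnan(counts.loc[2001])
        assert counts.loc[2000] == 1

    def test_18_dominates_20(self, rng):
        sst = rng.uniform(14, 22, size=730)
        s = series_from(sst, start="2000-01-01")
        c18 = days_above(s, 18.0)
        c20 = days_above(s, 20.0)
        ok = c18.notna()
        assert (c18[ok] >= c20[ok]).all()

    def test_inclusive_threshold(self):
        s = flat_series(start="2000-07-01", days=1, value=18.0)
        assert days_above(s, 18.0).loc[2000] == 1


class TestDetectEvents:
    def test_13_days_is_no_stress_event(self):
        s = series_from([18.5] * 13)
        assert detect_events(s, 18.0, 14, "stress") == []

    def test_14_days_at_exactly_18_is_one_event(self):
        s = series_from([18.0] * 14)
        events = detect_events(s, 18.0, 14, "stress")
        assert len(events) == 1
        assert events[0].length == 14

    def test_7_days_at_20_is_mortality(self):
        s = series_from([20.0] * 7)
        (e,) = detect_events(s, 20.0, 7, "mortality")
        assert e.kind == "mortality" and e.length == 7

    def test_20_day_run_is_one_maximal_event(self):
        s = series_from([20.5] * 20)
        events = detect_events(s, 20.0, 7, "mortality")
        assert len(events) == 1
        assert events[0].length == 20

    def test_cold_day_splits_run(self):
        vals = [18.5] * 14 + [17.0] + [18.5] * 14
        events = detect_events(series_from(vals), 18.0, 14, "stress")
        assert [e.length for e in events] == [14, 14]

    def test_data_gap_breaks_run(self):
        d1 = pd.date_range("2000-06-01", periods=10, freq="D")
        d2 = pd.date_range("2000-06-12", periods=10, freq="D")  # 1-day gap
        s = DailySSTSeries(
            dates=d1.append(d2), sst=np.full(20, 19.0)
        )
        events = detect_events(s, 18.0, 14, "stress")
        assert events == []
        events7 = detect_events(s, 18.0, 10, "stress")
        assert [e.length for e in events7] == [10, 10]

    def test_every_event_day_at_or_above_threshold(self, rng):
        sst = rng.uniform(15, 21, size=400)
        s = series_from(sst, start="2000-01-01")
        for e in detect_events(s, 18.0, 3, "stress"):
            i0 = s.dates.get_loc(e.start_date)
            i1 = s.dates.get_loc(e.end_date)
            assert (s.sst[i0 : i1 + 1] >= 18.0).all()
            # maximality
            if i0 > 0 and (s.dates[i0] - s.dates[i0 - 1]).days == 1:
                assert s.sst[i0 - 1] < 18.0
            if i1 < len(s) - 1 and (s.dates[i1 + 1] - s.dates[i1]).days == 1:
                assert s.sst[i1 + 1] < 18.0


class TestMannKendall:
    def test_strictly_increasing(self):
        r = mann_kendall([1, 2, 3, 4, 5, 6])
        assert r.tau == 1.0
        assert r.p_value < 0.05

    def test_antisymmetry(self, rng):
        x = rng.normal(size=12)
        a = mann_kendall(x)
        b = mann_kendall(-x)
        assert a.tau == pytest.approx(-b.tau)
        assert a.p_value == pytest.approx(b.p_value)

    def test_all_equal(self):
        r = mann_kendall([3.0] * 6)
        assert r.tau == 0.0 and r.p_value == 1.0

    def test_brute_force_enumeration_n8(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            r = mann_kendall(x)
            s = sum(
                np.sign(x[j] - x[i])
                for i, j in itertools.combinations(range(8), 2)
            )
            assert r.s == s
            assert r.tau == pytest.approx(s / (8 * 7 / 2))

    def test_tau_matches_scipy_kendalltau(self, rng):
        x = rng.integers(0, 5, size=15).astype(float)  # with ties
        t = np.arange(15, dtype=float)
        r = mann_kendall(x, t)
        tau, _ = stats.kendalltau(t, x)
        assert r.tau == pytest.approx(tau)

    def test_nan_years_dropped(self):
        r = mann_kendall([1, np.nan, 2, 3, 4], [0, 1, 2, 3, 4])
        assert r.n == 4 and r.tau == 1.0

    def test_too_few_years(self):
        with pytest.raises(ValueError, match=">= 4"):
            mann_kendall([1, 2, 3])

    def test_tau_sign_matches_sen_sign(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            r = mann_kendall(x)
            if r.sen_slope != 0:
                assert np.sign(r.tau) == np.sign(r.sen_slope)


class TestSenSlope:
    def test_exact_line(self):
        t = np.arange(30)
        assert sen_slope(0.36 * t + 5.0, t) == pytest.approx(0.36)

    def test_enumeration_example(self):
        assert sen_slope([1, 2, 4], [0, 1, 2]) == pytest.approx(1.5)

    def test_constant(self):
        assert sen_slope([2.0, 2.0, 2.0]) == 0.0

    def test_matches_scipy_theilslopes(self, rng):
        x = rng.normal(size=15)
        t = np.arange(15, dtype=float)
        assert sen_slope(x, t) == pytest.approx(
            stats.theilslopes(x, t).slope
        )

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            sen_slope([1.0])


class TestEventOddsTrend:
    def test_null_indicator_or_near_one(self, rng):
        t = np.arange(500)
        y = (rng.random(500) < 0.5).astype(float)
        r = event_odds_trend(y, t)
        assert r["odds_ratio"] == pytest.approx(1.0, abs=0.01)
        assert r["or_ci"][0] < 1.0 < r["or_ci"][1]

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t = np.arange(1961, 2021, dtype=float)
        p = 1 / (1 + np.exp(-(0.05 * (t - 1990))))
        y = (rng.random(60) < p).astype(float)
        r = event_odds_trend(y, t)
        X = sm.add_constant(t - t.mean())
        fit = sm.Logit(y, X).fit(disp=0)
        assert r["slope"] == pytest.approx(fit.params[1], abs=1e-6)
        assert r["se"] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            event_odds_trend([0.0] * 10, np.arange(10))

    def test_complete_separation_detected(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(SeparationError):
            event_odds_trend(y, np.arange(20))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            event_odds_trend([0.0, 0.5, 1.0, 1.0], np.arange(4))


class TestTrendRate:
    def test_exact_line(self):
        t = np.arange(1961, 2024)
        v = 0.033 * (t - 1961) + 10.0
        r = trend_rate(v, t, n_boot=0)
        assert r["rate_per_decade"] == pytest.approx(0.33, rel=1e-3)
        assert r["total_change"] == pytest.approx(0.033 * 62, rel=1e-3)

    def test_constant_series(self):
        t = np.arange(1961, 2024)
        r = trend_rate(np.full(t.size, 9.0), t, n_boot=0)
        assert r["rate_per_decade"] == pytest.approx(0.0, abs=1e-9)

    def test_period_subsetting(self):
        t = np.arange(1961, 2024)
        v = 0.05 * (t - 1961) + 8.0
        r = trend_rate(v, t, period=(1972, 2023), n_boot=0)
        assert r["total_change"] == pytest.approx(0.05 * 51, rel=1e-3)

    def test_period_outside_range_rejected(self):
        t = np.arange(1961, 2024)
        with pytest.raises(ValueError, match="period"):
            trend_rate(np.zeros(t.size), t, period=(1900, 2023), n_boot=0)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        t = np.arange(1961, 2024)
        v = 0.033 * (t - 1961) + 10.0 + rng.normal(0, 0.2, t.size)
        r = trend_rate(v, t, n_boot=100, seed=0)
        lo, hi = r["ci"]
        assert lo < 0.33 < hi or abs(r["rate_per_decade"] - 0.33) < 0.2


class TestAnomaliesAndCorrelation:
    def _annual(self, rng, years=range(1950, 2024)):
        idx = pd.Index(list(years), name="year")
        return pd.Series(rng.normal(10, 1, len(idx)), index=idx)

    def test_self_correlation(self, rng):
        a = self._annual(rng)
        r = anomalies_and_correlation(a, a)
        assert r["r"] == pytest.approx(1.0)

    def test_baseline_anomalies_average_zero(self, rng):
        a = self._annual(rng)
        b = self._annual(rng)
        out = anomalies_and_correlation(a, b, baseline_years=(1971, 2000))
        base = out["anomalies_a"].loc[1971:2000]
        assert base.mean() == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_pearson(self):
        years = pd.Index([1971, 1972, 1973, 1974, 1975])
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 6.0], index=years)
        b = pd.Series([2.0, 1.0, 4.0, 3.0, 5.0], index=years)
        out = anomalies_and_correlation(a, b, baseline_years=(1971, 1975))
        ax = a - a.mean()
        bx = b - b.mean()
        expected = (ax * bx).sum() / np.sqrt((ax**2).sum() * (bx**2).sum())
        assert out["r"] == pytest.approx(expected)

    def test_insufficient_overlap_rejected(self, rng):
        a = self._annual(rng, range(1971, 2001))
        b = self._annual(rng, range(1999, 2024))
        with pytest.raises(ValueError, match="overlapping years"):
            anomalies_and_correlation(a, b, baseline_years=(1971, 2000))

    def test_missing_baseline_rejected(self, rng):
        a = self._annual(rng, range(1971, 2001))
        b = self._annual(rng, range(2001, 2024))
        with pytest.raises(ValueError, match="baseline"):
            anomalies_and_correlation(a, b, baseline_years=(1971, 2000))


class TestAnnualMeans:
    def test_winter_spans_year_boundary(self):
        dates = pd.date_range("2000-12-01", "2001-02-28", freq="D")
        s = DailySSTSeries(dates=dates, sst=np.full(len(dates), 7.0))
        w = annual_means(s, "winter")
        assert list(w.index) == [2001]
        assert w.loc[2001] == pytest.approx(7.0)

    def test_summer_window(self):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        sst = np.where(np.isin(dates.month, (6, 7, 8)), 18.0, 10.0)
        s = DailySSTSeries(dates=dates, sst=sst)
        assert annual_means(s, "summer").loc[2000] == pytest.approx(18.0)

    def test_event_indicator(self):
        dates = pd.date_range("2000-01-01", "2002-12-31", freq="D")
        sst = np.full(len(dates), 15.0)
        idx = dates.get_loc(pd.Timestamp("2001-07-01"))
        sst[idx : idx + 14] = 18.5
        s = DailySSTSeries(dates=dates, sst=sst)
        events = detect_events(s, 18.0, 14, "stress")
        flag = annual_event_indicator(s, events)
        assert flag.loc[2001] == 1.0
        assert flag.loc[2000] == 0.0 and flag.loc[2002] == 0.0
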