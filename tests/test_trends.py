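import datetime as dt

import numpy as np
import pytest

from endsmonitor.trends import (
    DailySeries,
    crosstab_geo_subject,
    daily_counts,
    fit_trend,
    weekday_profile,
)
from .conftest import make_article


def series(counts, start=dt.date(2015, 1, 1)):
    end = start + dt.timedelta(days=len(counts) - 1)
    return DailySeries(start_date=start, end_date=end,
                       counts=np.asarray(counts, dtype=int))


class TestDailyCounts:
    def test_tally_with_zero_fill(self):
        day = dt.date(2015, 3, 2)
        arts = [make_article(id=f"a{i}", published_at=day) for i in range(3)]
        s = daily_counts(arts, dt.date(2015, 3, 1), dt.date(2015, 3, 5))
        assert list(s.counts) == [0, 3, 0, 0, 0]

    def test_empty_corpus_all_zero(self):
        s = daily_counts([], dt.date(2015, 1, 1), dt.date(2015, 1, 10))
        assert s.counts.sum() == 0 and len(s.counts) == 10

    def test_out_of_window_excluded_and_conservation(self):
        arts = [make_article(id=f"a{i}", published_at=dt.date(2015, 1, 1) + dt.timedelta(days=i))
                for i in range(20)]
        s = daily_counts(arts, dt.date(2015, 1, 5), dt.date(2015, 1, 14))
        assert s.counts.sum() == 10

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            daily_counts([], dt.date(2015, 2, 1), dt.date(2015, 1, 1))


class TestFitTrend:
    def test_constant_series(self):
        fit = fit_trend(series([5, 5, 5, 5]))
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(5.0)

    def test_exact_line(self):
        fit = fit_trend(series([0, 1, 2, 3]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(20, size=400).astype(float)
        fit = fit_trend(series(list(y)))
        t = np.arange(400.0)
        X = np.column_stack([np.ones(400), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_yearly_stats_definition(self):
        # 2 days of 2015, 3 days of 2016
        s = series([4, 6, 10, 20, 30], start=dt.date(2015, 12, 30))
        fit = fit_trend(s)
        stats = {y.year: y for y in fit.yearly}
        assert stats[2015].mean == pytest.approx(5.0)
        assert stats[2015].sd == pytest.approx(np.std([4, 6], ddof=1))
        assert stats[2016].mean == pytest.approx(20.0)
        assert stats[2015].partial and stats[2016].partial

    def test_single_day_year_has_no_sd(self):
        s = series([3, 7], start=dt.date(2015, 12, 31))
        stats = {y.year: y for y in fit_trend(s).yearly}
        assert stats[2015].sd is None
        assert stats[2016].sd is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(series([1]))


class TestWeekdayProfile:
    def test_constant_series_flat_profile(self):
        prof = weekday_profile(series([3] * 21))
        assert np.allclose(prof, 3.0)

    def test_monday_only(self):
        start = dt.date(2015, 1, 5)  # a Monday
        counts = [9 if i % 7 == 0 else 0 for i in range(21)]
        prof = weekday_profile(series(counts, start=start))
        assert prof[0] == pytest.approx(9.0)
        assert np.allclose(prof[1:], 0.0)

    def test_weighted_generator_profile_recovered(self):
        rng = np.random.default_rng(6)
        weights = np.array([3.0, 1, 1, 1, 1, 1, 0.5])
        start = dt.date(2015, 1, 5)  # Monday
        counts = [rng.poisson(10 * weights[i % 7]) for i in range(7 * 60)]
        prof = weekday_profile(series(counts, start=start))
        assert np.allclose(prof, 10 * weights, rtol=0.15)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            weekday_profile(series([1] * 6))


class TestCrosstab:
    def test_single_cell(self):
        ct = crosstab_geo_subject(["USA"] * 4, ["bans"] * 4)
        assert ct.loc["USA", "bans"] == pytest.approx(100.0)
        assert ct.loc["all", "bans"] == pytest.approx(100.0)

    def test_row_percentage_definition(self):
        geo = ["USA"] * 100
        subject = ["warnings"] * 31 + ["other"] * 69
        ct = crosstab_geo_subject(geo, subject)
        assert ct.loc["USA", "warnings"] == pytest.approx(31.0)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(12)
        geo = [str(g) for g in rng.choice(["USA", "GBR", "RUS", "MUL"], 600)]
        subject = [str(s) for s in rng.choice(["bans", "prices", "other"], 600)]
        ct = crosstab_geo_subject(geo, subject)
        assert np.allclose(ct.sum(axis=1).to_numpy(), 100.0, atol=1e-9)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(13)
        geo = [str(g) for g in rng.choice(["USA", "GBR", "RUS"], 300)]
        subject = [str(s) for s in rng.choice(["bans", "prices", "other"], 300)]
        ct = crosstab_geo_subject(geo, subject)
        for g in set(geo):
            row_n = sum(1 for x in geo if x == g)
            for s in set(subject):
                cell = sum(1 for x, y in zip(geo, subject) if x == g and y == s)
                assert ct.loc[g, s] == pytest.approx(100.0 * cell / row_n)

    def test_top_k_restriction(self):
        geo = ["USA"] * 5 + ["GBR"] * 3 + ["RUS"] * 1
        subject = ["bans"] * 9
        ct = crosstab_geo_subject(geo, subject, top_k=2)
        assert list(ct.index) == ["all", "USA", "GBR"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crosstab_geo_subject(["USA"], ["bans", "prices"])
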