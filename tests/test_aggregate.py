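"""Bucketing, ratios, trend fits and the weekly F test."""

import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from radsent.aggregate import (
    FTestMode,
    Granularity,
    bucket_labels,
    bucketize,
    count_ratio,
    cumulative_series,
    fit_trend,
    fukushima_weekly_ratios,
    share_of_total,
    shifted_mean_ratio,
    weekly_f_series,
    weekly_f_test,
)
from radsent.corpus_io import DEFAULT_WINDOW, JST


def _frame(times_scores, group="TARGET"):
    return pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex([t for t, _ in times_scores], tz=JST),
            "t_pn": [s for _, s in times_scores],
            "group": group,
        }
    )


def _t(day, hour=12):
    return DEFAULT_WINDOW.start + timedelta(days=day, hours=hour)


# --- bucketize --------------------------------------------------------------

def test_bucketize_day_symmetric_cancellation():
    df = _frame([(_t(0), 0.0), (_t(0), 0.3), (_t(0), -0.3)])
    out = bucketize(df, Granularity.DAY)
    assert len(out) == 1
    assert out.loc[0, "n"] == 3 and out.loc[0, "mean_tpn"] == pytest.approx(0.0)


def test_bucketize_single_tweet_mean_is_its_score():
    out = bucketize(_frame([(_t(3), -0.42)]), Granularity.DAY)
    assert out.loc[0, "n"] == 1 and out.loc[0, "mean_tpn"] == pytest.approx(-0.42)


def test_bucketize_weekly_conservation():
    rows = [(_t(d), 0.1 * (d % 3 - 1)) for d in range(14) for _ in range(d % 4)]
    df = _frame(rows)
    out = bucketize(df, Granularity.WEEK)
    assert out["n"].sum() == len(df)
    assert set(out["bucket"]) <= {"W00", "W01"}


def test_weeks_anchor_at_event_not_iso():
    # 2011-03-11 was a Friday; the first anchored week is Mar 11..17
    assert bucket_labels(pd.Series(pd.DatetimeIndex([_t(6)], tz=JST)), Granularity.WEEK)[0] == "W00"
    assert bucket_labels(pd.Series(pd.DatetimeIndex([_t(7)], tz=JST)), Granularity.WEEK)[0] == "W01"


def test_minute_buckets_calendar_aligned():
    ts = pd.Series(pd.DatetimeIndex([DEFAULT_WINDOW.start + timedelta(minutes=90, seconds=30)], tz=JST))
    assert bucket_labels(ts, Granularity.MINUTE)[0] == "2011-03-11 01:30"


def test_weekly_mean_equals_weighted_daily_means():
    rng = np.random.default_rng(11)
    rows = []
    for d in range(7):
        for _ in range(int(rng.integers(1, 8))):
            rows.append((_t(d, hour=int(rng.integers(0, 24))), float(rng.uniform(-1, 1))))
    df = _frame(rows)
    daily = bucketize(df, Granularity.DAY)
    weekly = bucketize(df, Granularity.WEEK)
    weighted = (daily["mean_tpn"] * daily["n"]).sum() / daily["n"].sum()
    assert weekly.loc[0, "mean_tpn"] == pytest.approx(weighted, abs=1e-12)


def test_empty_cells_absent_not_zero():
    df = _frame([(_t(0), 0.5), (_t(2), -0.5)])
    out = bucketize(df, Granularity.DAY)
    assert list(out["bucket"]) == ["2011-03-11", "2011-03-13"]  # no zero-filled Mar 12


# --- cumulative -------------------------------------------------------------

def test_cumulative_prefix_sums():
    daily = pd.DataFrame({"bucket": ["d1", "d2", "d3"], "sum_tpn": [-1.0, -2.0, 0.5]})
    out = cumulative_series(daily)
    assert list(out["cum_sum_tpn"]) == [-1.0, -3.0, -2.5]


def test_cumulative_last_equals_total():
    rng = np.random.default_rng(5)
    daily = pd.DataFrame({"bucket": [f"d{i:02d}" for i in range(30)], "sum_tpn": rng.normal(size=30)})
    out = cumulative_series(daily)
    assert out["cum_sum_tpn"].iloc[-1] == pytest.approx(daily["sum_tpn"].sum())


# --- ratios -----------------------------------------------------------------

@pytest.mark.parametrize("nf, no, expected", [(50, 100, 0.5), (0, 100, 0.0), (77, 77, 1.0)])
def test_count_ratio(nf, no, expected):
    assert count_ratio(nf, no) == pytest.approx(expected)


def test_count_ratio_zero_denominator_is_missing():
    assert math.isnan(count_ratio(5, 0))


@pytest.mark.parametrize(
    "mf, mo, expected",
    [(-0.3, -0.3, 1.0), (-1.0, 0.2, 0.0), (0.0, -0.5, 2.0)],
)
def test_shifted_mean_ratio(mf, mo, expected):
    assert shifted_mean_ratio(mf, mo) == pytest.approx(expected)


def test_shifted_mean_ratio_undefined_at_minus_one():
    assert math.isnan(shifted_mean_ratio(0.0, -1.0))


@given(
    st.floats(min_value=-0.99, max_value=1.0),
    st.floats(min_value=-0.99, max_value=1.0),
    st.floats(min_value=0.001, max_value=0.5),
)
@settings(derandomize=True, max_examples=200)
def test_shifted_ratio_monotone(mf, mo, eps):
    base = shifted_mean_ratio(mf, mo)
    if mf + eps <= 1.0:
        assert shifted_mean_ratio(mf + eps, mo) > base  # increasing in mean_f
    assert shifted_mean_ratio(mf, mo + eps) < base      # decreasing in mean_o


# --- trends -----------------------------------------------------------------

def test_fit_trend_exact_line():
    t = np.arange(10)
    fit = fit_trend(t, 2 * t + 1)
    assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(1.0)
    assert fit.n_points == 10


def test_fit_trend_constant_series():
    assert fit_trend(np.arange(5), np.full(5, 0.7)).slope == pytest.approx(0.0)


def test_fit_trend_recovers_simulated_slope():
    rng = np.random.default_rng(42)
    t = np.arange(100, dtype=float)
    y = 3.0 * t + rng.normal(0, 0.1, size=100)
    fit = fit_trend(t, y)
    assert abs(fit.slope - 3.0) <= 3 * fit.stderr_slope


def test_fit_trend_degenerate_abscissae():
    with pytest.raises(ValueError):
        fit_trend([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


# --- F test -----------------------------------------------------------------

def test_anova_hand_computed_example():
    res = weekly_f_test([0.0, 0.2], [1.0, 1.2])
    assert res.f_stat == pytest.approx(50.0, abs=1e-9)
    assert (res.df1, res.df2) == (1, 2)
    assert res.p_value == pytest.approx(0.01942, abs=5e-5)
    assert res.significant


def test_anova_identical_samples():
    res = weekly_f_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert res.f_stat == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)


def test_small_group_yields_missing():
    assert weekly_f_test([0.1], [0.2, 0.3]) is None


def test_anova_matches_scipy_and_t_squared():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(-0.5, 0.2, size=int(rng.integers(5, 40)))
        b = rng.normal(-0.4, 0.2, size=int(rng.integers(5, 40)))
        res = weekly_f_test(a, b)
        f_ref, p_ref = stats.f_oneway(a, b)
        assert res.f_stat == pytest.approx(f_ref, rel=1e-9)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)
        t_ref = stats.ttest_ind(a, b).statistic
        assert res.f_stat == pytest.approx(t_ref**2, rel=1e-9)


def test_var_ratio_mode():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 2.0, size=30)
    b = rng.normal(0, 1.0, size=25)
    res = weekly_f_test(a, b, mode=FTestMode.VAR_RATIO)
    assert res.f_stat == pytest.approx(np.var(a, ddof=1) / np.var(b, ddof=1))
    assert (res.df1, res.df2) == (29, 24)
    assert 0.0 <= res.p_value <= 1.0


def test_weekly_f_series_counts_and_missing():
    rows = []
    for d in range(7):  # week 0: both groups populated
        rows.append((_t(d), 0.1 * d))
    df_a = _frame(rows, group="TARGET")
    df_b = _frame([(_t(d), -0.1 * d) for d in range(7)], group="RT_GROUP")
    df_c = _frame([(_t(8), 0.5)], group="TARGET")  # week 1: RT side empty
    scored = pd.concat([df_a, df_b, df_c], ignore_index=True)
    out = weekly_f_series(scored)
    assert list(out["bucket"]) == ["W00", "W01"]
    assert math.isnan(out.loc[1, "f_stat"])  # missing, not fabricated


# --- shares -----------------------------------------------------------------

@pytest.mark.parametrize(
    "sub, total, expected",
    [(1797, 34173, 5.26), (0, 10, 0.0), (10, 10, 100.0)],
)
def test_share_of_total(sub, total, expected):
    assert share_of_total(sub, total) == pytest.approx(expected)


def test_share_of_total_contract():
    with pytest.raises(ValueError):
        share_of_total(5, 0)
    with pytest.raises(ValueError):
        share_of_total(11, 10)


def test_fukushima_weekly_ratios_table():
    rows_f = [(_t(d), -0.4) for d in range(3)]
    rows_o = [(_t(d), -0.6) for d in range(6)]
    df = pd.concat(
        [_frame(rows_f).assign(is_fukushima=True), _frame(rows_o).assign(is_fukushima=False)],
        ignore_index=True,
    )
    out = fukushima_weekly_ratios(df)
    assert len(out) == 1
    assert out.loc[0, "count_ratio"] == pytest.approx(0.5)
    assert out.loc[0, "shifted_mean_ratio"] == pytest.approx(0.6 / 0.4)
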