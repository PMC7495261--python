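"""Analytical surfaces over scored tweets: bucketed counts and means,
cumulative sums, Fukushima-vs-others ratios, OLS trend lines, weekly F tests.

All bucketing is done in JST.  Days and minutes are calendar-aligned;
weeks are 7-day half-open intervals anchored at the study-window start
(2011-03-11), not ISO weeks, so that week 0 begins with the event itself.
Empty cells are reported as missing, never as zero — zero is a meaningful
sentiment value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import DEFAULT_WINDOW, JST, StudyWindow


class Granularity(str, Enum):
    MINUTE = "minute"
    DAY = "day"
    WEEK = "week"


@dataclass(frozen=True)
class TrendFit:
    """Ordinary-least-squares line fitted to a bucket series."""

    slope: float
    intercept: float
    stderr_slope: float
    n_points: int


@dataclass(frozen=True)
class FTestResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def bucket_labels(
    timestamps: pd.Series, granularity: Granularity, window: StudyWindow = DEFAULT_WINDOW
) -> pd.Series:
    """Map JST timestamps to bucket labels for the requested granularity."""
    ts = pd.to_datetime(timestamps)
    ts = ts.dt.tz_convert(JST)
    if granularity is Granularity.DAY:
        return ts.dt.strftime("%Y-%m-%d")
    if granularity is Granularity.MINUTE:
        return ts.dt.strftime("%Y-%m-%d %H:%M")
    delta = ts - pd.Timestamp(window.start)
    week = (delta.dt.days // 7).astype(int)
    return week.map(lambda w: f"W{w:02d}")


def bucketize(
    scored: pd.DataFrame,
    granularity: Granularity | str,
    by: Sequence[str] = (),
    value_col: str = "t_pn",
    window: StudyWindow = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-(bucket × strata) cell counts, sums and means of the score.

    ``by`` names extra stratification columns already present in ``scored``
    (e.g. "group", "region").  Cells with no tweets are simply absent.
    """
    granularity = Granularity(granularity)
    df = scored.copy()
    df["bucket"] = bucket_labels(df["timestamp"], granularity, window)
    keys = ["bucket", *by]
    g = df.groupby(keys, sort=True, observed=True)[value_col]
    out = g.agg(n="count", sum_tpn="sum", mean_tpn="mean").reset_index()
    out["sum_tpn"] = out["sum_tpn"].astype(float)
    return out


def cumulative_series(daily: pd.DataFrame, value_col: str = "sum_tpn") -> pd.DataFrame:
    """Running (prefix) sum over a sorted bucket series."""
    out = daily.sort_values("bucket").reset_index(drop=True).copy()
    out["cum_sum_tpn"] = out[value_col].cumsum()
    return out


def count_ratio(n_fukushima: float, n_others: float) -> float:
    """Fukushima / others tweet-count ratio; NaN (logged as missing) if no others."""
    if n_others == 0:
        return math.nan
    return n_fukushima / n_others


def shifted_mean_ratio(mean_f: float, mean_o: float) -> float:
    """(mean_f + 1) / (mean_o + 1): both means live in [−1, 1], so shifting by
    one makes the ratio of the (non-negative) shifted means comparable across
    weeks.  Undefined (NaN) when the denominator mean is exactly −1; note the
    ratio is unbounded above as mean_o approaches −1, it is not confined to
    [0, 2]."""
    if math.isnan(mean_f) or math.isnan(mean_o) or mean_o == -1.0:
        return math.nan
    return (mean_f + 1.0) / (mean_o + 1.0)


def fit_trend(t: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS line through (t, y); the dashed "linear approximation" of a series."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    if len(t) < 2 or np.unique(t).size < 2:
        raise ValueError("trend fit needs >= 2 points with distinct abscissae")
    res = stats.linregress(t, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        n_points=int(len(t)),
    )


class FTestMode(str, Enum):
    ANOVA = "anova"
    VAR_RATIO = "var"


def weekly_f_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alpha: float = 0.05,
    mode: FTestMode | str = FTestMode.ANOVA,
) -> Optional[FTestResult]:
    """F test between two groups' tweet-level scores for one week.

    ANOVA mode (default) is a one-way between-groups F on the two samples —
    for two groups this equals the squared pooled t statistic, i.e. a test of
    mean divergence.  VAR_RATIO mode is the classical variance-ratio F
    (two-sided p).  A group with fewer than two tweets yields None (missing
    week), never a fabricated statistic.
    """
    mode = FTestMode(mode)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        return None
    if mode is FTestMode.ANOVA:
        grand = (a.sum() + b.sum()) / (n_a + n_b)
        ssb = n_a * (a.mean() - grand) ** 2 + n_b * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        df1, df2 = 1, n_a + n_b - 2
        if ssw == 0.0:
            f = math.inf if ssb > 0 else 0.0
        else:
            f = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    else:
        var_a = a.var(ddof=1)
        var_b = b.var(ddof=1)
        if var_b == 0.0:
            return None
        f = var_a / var_b
        df1, df2 = n_a - 1, n_b - 1
        p = float(2.0 * min(stats.f.sf(f, df1, df2), stats.f.cdf(f, df1, df2)))
        p = min(p, 1.0)
    return FTestResult(f_stat=float(f), df1=df1, df2=df2, p_value=p, alpha=alpha)


def weekly_f_series(
    scored: pd.DataFrame,
    alpha: float = 0.05,
    mode: FTestMode | str = FTestMode.ANOVA,
    group_col: str = "group",
    groups: tuple[str, str] = ("TARGET", "RT_GROUP"),
    window: StudyWindow = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-week F tests between two groups' tweet-level scores."""
    df = scored.copy()
    df["bucket"] = bucket_labels(df["timestamp"], Granularity.WEEK, window)
    rows = []
    for bucket, sub in df.groupby("bucket", sort=True):
        a = sub.loc[sub[group_col] == groups[0], "t_pn"].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], "t_pn"].to_numpy()
        res = weekly_f_test(a, b, alpha=alpha, mode=mode)
        if res is None:
            rows.append(
                {"bucket": bucket, "f_stat": math.nan, "df1": 0, "df2": 0,
                 "p_value": math.nan, "significant": False, "n_a": len(a), "n_b": len(b)}
            )
        else:
            rows.append(
                {"bucket": bucket, "f_stat": res.f_stat, "df1": res.df1, "df2": res.df2,
                 "p_value": res.p_value, "significant": res.significant,
                 "n_a": len(a), "n_b": len(b)}
            )
    return pd.DataFrame(rows)


def share_of_total(subcount: int, total: int) -> float:
    """Percentage share of a subcount, to two decimals (e.g. 1797/34173 → 5.26)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if subcount > total:
        raise ValueError("subcount exceeds total")
    return round(100.0 * subcount / total, 2)


def fukushima_weekly_ratios(
    scored: pd.DataFrame,
    fukushima_col: str = "is_fukushima",
    window: StudyWindow = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Weekly Fukushima-vs-others count ratio and +1-shifted mean ratio.

    Expects a boolean/NA column marking geolocated tweets as Fukushima or
    not; tweets without any prefecture are excluded upstream by passing only
    geolocated rows.
    """
    df = scored.copy()
    df["bucket"] = bucket_labels(df["timestamp"], Granularity.WEEK, window)
    rows = []
    for bucket, sub in df.groupby("bucket", sort=True):
        fuku = sub.loc[sub[fukushima_col].astype(bool), "t_pn"]
        other = sub.loc[~sub[fukushima_col].astype(bool), "t_pn"]
        mean_f = float(fuku.mean()) if len(fuku) else math.nan
        mean_o = float(other.mean()) if len(other) else math.nan
        rows.append(
            {
                "bucket": bucket,
                "n_fukushima": int(len(fuku)),
                "n_others": int(len(other)),
                "count_ratio": count_ratio(len(fuku), len(other)),
                "mean_fukushima": mean_f,
                "mean_others": mean_o,
                "shifted_mean_ratio": shifted_mean_ratio(mean_f, mean_o),
            }
        )
    return pd.DataFrame(rows)
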