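#!/usr/bin/env python
"""Weekly surfaces: group means, F tests, Fukushima-vs-others ratios, trends.

Reads scratch/analysis/geoparsed.csv (from 04) and writes the weekly
statistics the analysis turns on: per-group weekly mean semantic
orientation with OLS trend lines, weekly target-vs-RT ANOVA F tests at
α = .05, and the weekly Fukushima/others count and +1-shifted mean ratios.
"""

from pathlib import Path

import pandas as pd

from radsent.aggregate import (
    Granularity,
    bucketize,
    fit_trend,
    fukushima_weekly_ratios,
    weekly_f_series,
)
from radsent.corpus_io import JST
from radsent.geoparse import Prefecture

WORKDIR = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    scored = pd.read_csv(WORKDIR / "geoparsed.csv", keep_default_na=False)
    scored["timestamp"] = pd.to_datetime(scored["timestamp"]).dt.tz_convert(JST)
    RESULTS.mkdir(parents=True, exist_ok=True)

    weekly = bucketize(scored, Granularity.WEEK, by=("group",))
    weekly.to_csv(RESULTS / "weekly_mean_by_group.csv", index=False)

    trend_rows = []
    for grp, sub in weekly.groupby("group"):
        t = sub["bucket"].str.removeprefix("W").astype(int)
        fit = fit_trend(t, sub["mean_tpn"])
        trend_rows.append({"series": grp, "slope_per_week": fit.slope,
                           "intercept": fit.intercept, "stderr": fit.stderr_slope})
        print(f"{grp}: weekly-mean trend {fit.slope:+.5f}/week (se {fit.stderr_slope:.5f})")

    ftests = weekly_f_series(scored, alpha=0.05)
    ftests.to_csv(RESULTS / "weekly_f_tests.csv", index=False)
    n_sig = int(ftests["significant"].sum())
    print(f"weekly target-vs-RT F tests: {n_sig} of {len(ftests)} weeks significant at α=.05")

    geo = scored[scored["prefectures"] != ""].copy()
    geo["is_fukushima"] = geo["prefectures"].str.contains(Prefecture.FUKUSHIMA.value)
    ratios = fukushima_weekly_ratios(geo)
    ratios.to_csv(RESULTS / "weekly_fukushima_ratios.csv", index=False)
    valid = ratios.dropna(subset=["count_ratio"])
    t = valid["bucket"].str.removeprefix("W").astype(int)
    fit = fit_trend(t, valid["count_ratio"])
    trend_rows.append({"series": "fukushima_count_ratio", "slope_per_week": fit.slope,
                       "intercept": fit.intercept, "stderr": fit.stderr_slope})
    print(f"Fukushima/others count ratio: trend {fit.slope:+.5f}/week; "
          f"final-week ratio {valid['count_ratio'].iloc[-1]:.3f}")

    pd.DataFrame(trend_rows).to_csv(RESULTS / "weekly_trends.csv", index=False)


if __name__ == "__main__":
    main()
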