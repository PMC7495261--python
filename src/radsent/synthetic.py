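"""Synthetic radiation-tweet stream with recorded ground truth.

The generator emulates the statistical regimes of the one-year post-accident
stream the pipeline is built for: a Poisson daily volume with event-driven
spikes decaying exponentially, per-tweet semantic-orientation scores drawn
from a truncated normal whose mean drifts linearly per day, a bot/RT
subpopulation with a constant negative sentiment offset, and region mentions
whose Fukushima share follows a logistic time trend.

Scores are *realized as actual lexicon tokens*: each tweet's text is
assembled from fixture-lexicon words (on a 0.05 value grid) chosen so that
its exact T_pn under the builtin tokenizer equals the drawn target score,
up to grid rounding (≤ 0.025 on the sum) and feasibility clamping (a mean
beyond ±k/W_c cannot be realized with k scoring words; the nearest
achievable value is used).  Both the drawn target and the realized score are
recorded in the truth table, so the sentiment module is exercised
end-to-end rather than bypassed with attached labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import DEFAULT_WINDOW, JST, StudyWindow, Tweet
from .geoparse import Gazetteer, Prefecture, default_gazetteer
from .sentiment import Lexicon, fixture_lexicon

_GRID_STEP = 0.05  # fixture lexicon carries one word per value on this grid


@dataclass(frozen=True)
class EventSpike:
    """A volume spike: magnitude added on the event day, halving every half_life."""

    day: date
    magnitude: float
    half_life_days: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated stream.

    Defaults give ≈100k tweets over the year (a ~1:190 scale of the real
    stream), an RT group near half the corpus, a negative baseline sentiment
    drifting mildly positive, and a Fukushima share of geolocated tweets
    rising from about 0.20.
    """

    window: StudyWindow = field(default_factory=StudyWindow)
    base_volume: float = 450.0          # expected tweets/day at t=0
    volume_decay: float = 0.004         # per-day exponential decay rate
    events: tuple[EventSpike, ...] = (
        EventSpike(date(2011, 3, 12), 1500.0, 2.0),
        EventSpike(date(2011, 3, 15), 2000.0, 2.0),
        EventSpike(date(2011, 3, 23), 1000.0, 3.0),
    )
    sentiment_base: float = -0.55       # mean T_pn at t=0
    sentiment_slope: float = 0.0004     # per-day drift of the mean
    bot_fraction: float = 0.12
    rt_fraction: float = 0.40
    bot_sentiment_offset: float = -0.10  # added to the mean for bot/RT tweets
    geo_fraction: float = 0.33          # probability a tweet names a region
    fukushima_share_intercept: float = -1.386  # logit of the t=0 Fukushima share
    fukushima_share_slope: float = 0.004       # per-day logit drift
    noise_sd: float = 0.12              # per-tweet score dispersion
    n_scoring_words: int = 12           # lexicon words carrying the score
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        """Build from plain YAML/JSON data (event dates as ISO strings)."""
        raw = dict(raw)
        events = []
        for ev in raw.pop("events", cls.events):
            if isinstance(ev, EventSpike):
                events.append(ev)
            elif isinstance(ev, dict):
                d = ev["day"]
                d = d if isinstance(d, date) else date.fromisoformat(str(d))
                events.append(EventSpike(d, float(ev["magnitude"]), float(ev["half_life_days"])))
            else:
                d, mag, hl = ev
                d = d if isinstance(d, date) else date.fromisoformat(str(d))
                events.append(EventSpike(d, float(mag), float(hl)))
        return cls(events=tuple(events), **raw)

    def __post_init__(self) -> None:
        for name in ("bot_fraction", "rt_fraction", "geo_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bot_fraction + self.rt_fraction > 1.0:
            raise ValueError("bot_fraction + rt_fraction must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def expected_intensity(config: SyntheticConfig) -> np.ndarray:
    """Expected tweets per day over the window (decay + event spikes)."""
    n = config.window.n_days
    t = np.arange(n, dtype=float)
    lam = config.base_volume * np.exp(-config.volume_decay * t)
    start = config.window.start.date()
    for ev in config.events:
        d0 = (ev.day - start).days
        mask = t >= d0
        lam[mask] += ev.magnitude * np.exp2(-(t[mask] - d0) / ev.half_life_days)
    return lam


def _truncated_normal(rng: np.random.Generator, mu: np.ndarray, sd: float) -> np.ndarray:
    """Normal(mu, sd) truncated to [−1, 1], elementwise, via inverse-CDF."""
    if sd == 0.0:
        return np.clip(mu, -1.0, 1.0)
    from scipy.stats import norm

    lo = norm.cdf((-1.0 - mu) / sd)
    hi = norm.cdf((1.0 - mu) / sd)
    u = rng.uniform(lo, hi)
    return mu + sd * norm.ppf(u)


def _grid_vocabulary(lexicon: Lexicon) -> dict[int, str]:
    """One unmasked lexicon word per 0.05 grid value, index −20 … 20."""
    grid: dict[int, str] = {}
    for word in sorted(lexicon.entries):
        if word in lexicon.masked:
            continue
        v = lexicon.entries[word]
        idx = round(v / _GRID_STEP)
        if abs(v - idx * _GRID_STEP) < 1e-9 and idx not in grid:
            grid[idx] = word
    missing = [i for i in range(-20, 21) if i not in grid]
    if missing:
        raise ValueError(f"lexicon lacks grid values at indices {missing}")
    return grid


def _realize_scores(
    target_sum: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pick k grid indices per tweet whose values sum as close as the grid
    allows to target_sum.  Greedy: each slot takes the grid value nearest the
    mean of the remaining deficit, so the final residual is ≤ half a step."""
    n = len(target_sum)
    rem = target_sum.astype(float).copy()
    indices = np.empty((n, k), dtype=np.int64)
    for j in range(k):
        v = np.clip(rem / (k - j), -1.0, 1.0)
        idx = np.rint(v / _GRID_STEP).astype(np.int64)
        indices[:, j] = idx
        rem -= idx * _GRID_STEP
    achieved = target_sum - rem
    return indices, achieved


_KEYWORDS = ("放射線", "放射能", "放射性物質")
_FUKUSHIMA_WORDS = ("福島", "福島県", "福島市")


def generate_corpus(
    config: SyntheticConfig,
    lexicon: Optional[Lexicon] = None,
    gazetteer: Optional[Gazetteer] = None,
) -> tuple[list[Tweet], pd.DataFrame]:
    """Generate the corpus and its ground-truth table.

    Same config (including seed) ⇒ byte-identical corpus.  Every tweet
    contains exactly one radiation keyword (masked, so it carries no score);
    bot tweets get "…bot" handles, retweets get an "RT @…: " prefix (whose
    "RT" token counts toward W_c and is accounted for), and geolocated
    tweets carry one region word from the packaged gazetteer.
    """
    lex = lexicon if lexicon is not None else fixture_lexicon()
    gaz = gazetteer if gazetteer is not None else default_gazetteer()
    grid = _grid_vocabulary(lex)
    other_words = sorted(
        w
        for w, p in gaz.place_names.items()
        if p not in (Prefecture.FUKUSHIMA, Prefecture.OTHER)
    )
    word_pref = {w: p.value for w, p in gaz.place_names.items()}

    rng = np.random.default_rng(config.seed)
    lam = expected_intensity(config)
    day_counts = rng.poisson(lam)
    n = int(day_counts.sum())
    k = config.n_scoring_words

    day_idx = np.repeat(np.arange(len(lam)), day_counts)
    seconds = rng.integers(0, 86400, size=n)
    order = np.lexsort((seconds, day_idx))
    day_idx, seconds = day_idx[order], seconds[order]
    t_days = day_idx + seconds / 86400.0

    u = rng.random(n)
    is_bot = u < config.bot_fraction
    is_rt = (~is_bot) & (u < config.bot_fraction + config.rt_fraction)
    in_rt_group = is_bot | is_rt

    mu = config.sentiment_base + config.sentiment_slope * t_days
    mu = mu + np.where(in_rt_group, config.bot_sentiment_offset, 0.0)
    target = _truncated_normal(rng, mu, config.noise_sd)

    is_geo = rng.random(n) < config.geo_fraction
    share = 1.0 / (1.0 + np.exp(-(config.fukushima_share_intercept
                                  + config.fukushima_share_slope * t_days)))
    is_fuku = is_geo & (rng.random(n) < share)

    # W_c seen by the scorer: k grid words + the keyword (+ region word, + "RT")
    w_c = k + 1 + is_geo.astype(int) + is_rt.astype(int)
    indices, achieved_sum = _realize_scores(target * w_c, k)
    realized = achieved_sum / w_c

    keyword_pick = rng.integers(0, len(_KEYWORDS), size=n)
    keyword_slot = rng.integers(0, k + 1, size=n)
    fuku_pick = rng.integers(0, len(_FUKUSHIMA_WORDS), size=n)
    other_pick = rng.integers(0, len(other_words), size=n)
    author = rng.integers(0, 20000, size=n)
    rt_source = rng.integers(0, 20000, size=n)

    tweets: list[Tweet] = []
    truth_rows = []
    start = config.window.start
    for i in range(n):
        words = [grid[int(ix)] for ix in indices[i]]
        words.insert(int(keyword_slot[i]), _KEYWORDS[keyword_pick[i]])
        region = ""
        if is_geo[i]:
            region = (
                _FUKUSHIMA_WORDS[fuku_pick[i]] if is_fuku[i] else other_words[other_pick[i]]
            )
            words.append(region)
        body = " ".join(words)
        if is_bot[i]:
            handle = f"u{author[i]}bot"
            text = body
            reason = "BOT_ACCOUNT"
        elif is_rt[i]:
            handle = f"u{author[i]}"
            text = f"RT @u{rt_source[i]}: {body}"
            reason = "STARTS_WITH_RT"
        else:
            handle = f"u{author[i]}"
            text = body
            reason = ""
        ts = start + timedelta(days=int(day_idx[i]), seconds=int(seconds[i]))
        tid = f"t{i:08d}"
        tweets.append(Tweet(tid, ts, handle, text))
        truth_rows.append(
            {
                "tweet_id": tid,
                "day": int(day_idx[i]),
                "group": "RT_GROUP" if in_rt_group[i] else "TARGET",
                "rt_reason": reason,
                "mu": float(mu[i]),
                "target_score": float(target[i]),
                "realized_score": float(realized[i]),
                "w_c": int(w_c[i]),
                "prefecture": word_pref.get(region, "") if region else "",
            }
        )
    truth = pd.DataFrame(truth_rows)
    return tweets, truth


def recovery_report(
    scored: pd.DataFrame, truth: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Compare pipeline estimates against the generating parameters.

    Three recoveries: the weekly target-group mean trend slope against
    7 × sentiment_slope (tolerance: 3 fitted standard errors), the RT-vs-
    target mean gap against bot_sentiment_offset (tolerance ±0.02), and the
    sign of the weekly Fukushima count-ratio trend against the configured
    logistic slope.
    """
    from .aggregate import Granularity, bucketize, count_ratio, fit_trend

    rows = []

    weekly = bucketize(
        scored[scored["group"] == "TARGET"], Granularity.WEEK, window=config.window
    )
    t = weekly["bucket"].str.removeprefix("W").astype(int)
    fit = fit_trend(t, weekly["mean_tpn"])
    true_slope = 7.0 * config.sentiment_slope
    rows.append(
        {
            "parameter": "weekly_mean_slope",
            "true": true_slope,
            "estimated": fit.slope,
            "tolerance": 3.0 * fit.stderr_slope,
            "within_tolerance": abs(fit.slope - true_slope) <= 3.0 * fit.stderr_slope,
        }
    )

    gap = (
        scored.loc[scored["group"] == "RT_GROUP", "t_pn"].mean()
        - scored.loc[scored["group"] == "TARGET", "t_pn"].mean()
    )
    rows.append(
        {
            "parameter": "bot_sentiment_offset",
            "true": config.bot_sentiment_offset,
            "estimated": float(gap),
            "tolerance": 0.02,
            "within_tolerance": abs(gap - config.bot_sentiment_offset) <= 0.02,
        }
    )

    geo = scored[scored["prefectures"].astype(bool)].copy()
    geo["is_fukushima"] = geo["prefectures"].str.contains(Prefecture.FUKUSHIMA.value)
    weekly_geo = geo.assign(
        bucket=lambda d: (
            (pd.to_datetime(d["timestamp"]).dt.tz_convert(JST) - pd.Timestamp(config.window.start))
            .dt.days
            // 7
        )
    )
    ratio_rows = []
    for wk, sub in weekly_geo.groupby("bucket"):
        r = count_ratio(int(sub["is_fukushima"].sum()), int((~sub["is_fukushima"]).sum()))
        if not math.isnan(r):
            ratio_rows.append((wk, r))
    rt = fit_trend([r[0] for r in ratio_rows], [r[1] for r in ratio_rows])
    if config.fukushima_share_slope == 0:
        ok = abs(rt.slope) <= 3.0 * rt.stderr_slope
    else:
        ok = math.copysign(1.0, rt.slope) == math.copysign(1.0, config.fukushima_share_slope)
    rows.append(
        {
            "parameter": "fukushima_share_trend_sign",
            "true": math.copysign(1.0, config.fukushima_share_slope)
            if config.fukushima_share_slope
            else 0.0,
            "estimated": rt.slope,
            "tolerance": 3.0 * rt.stderr_slope,
            "within_tolerance": bool(ok),
        }
    )
    return pd.DataFrame(rows)
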