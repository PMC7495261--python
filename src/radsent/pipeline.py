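"""One reproducible run: simulate/read → group → score → geoparse → aggregate.

``run_pipeline`` executes every stage in order, writes each intermediate and
final table as CSV/JSONL under the output directory, and finishes with a
``manifest.json`` recording the configuration, per-stage row counts and
warnings.  A rerun with the same configuration and inputs reproduces the
outputs byte for byte; on a stage failure the manifest is still written with
the failing stage named and a FAILED marker.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    FTestMode,
    Granularity,
    bucketize,
    cumulative_series,
    fukushima_weekly_ratios,
    fit_trend,
    weekly_f_series,
)
from .corpus_io import DEFAULT_WINDOW, StudyWindow, corpus_frame, read_corpus, write_corpus
from .geoparse import (
    Gazetteer,
    Prefecture,
    default_gazetteer,
    default_population,
    load_gazetteer,
    load_population,
    per_capita_rate,
    resolve_prefectures,
)
from .grouping import DEFAULT_KEYWORDS, group_corpus
from .sentiment import (
    DEFAULT_MASK,
    DictionaryTokenizer,
    Lexicon,
    fixture_lexicon,
    load_lexicon,
    preprocess,
    score_tokens,
)
from .synthetic import SyntheticConfig, generate_corpus

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Leave ``corpus_path`` unset to simulate a corpus from ``synthetic`` (the
    seed lives inside the synthetic config); packaged fixture tables are used
    wherever a path is omitted.
    """

    out_dir: Path
    corpus_path: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    lexicon_path: Optional[Path] = None
    gazetteer_path: Optional[Path] = None
    postal_path: Optional[Path] = None
    phone_path: Optional[Path] = None
    population_path: Optional[Path] = None
    keywords: tuple[str, ...] = tuple(sorted(DEFAULT_KEYWORDS))
    mask: tuple[str, ...] = tuple(sorted(DEFAULT_MASK))
    alpha: float = 0.05
    f_test_mode: str = FTestMode.ANOVA.value
    count_all_tokens: bool = False
    window: StudyWindow = field(default_factory=StudyWindow)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig.from_dict(syn)
        paths = {
            k: Path(v)
            for k, v in list(raw.items())
            if k.endswith(("_path", "_dir")) and v is not None
        }
        raw.update(paths)
        return cls(synthetic=syn, **raw)

    def to_manifest(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, StudyWindow):
                v = {"start": v.start.isoformat(), "end": v.end.isoformat()}
            elif isinstance(v, SyntheticConfig):
                v = json.loads(
                    json.dumps(dataclasses.asdict(v), default=str)
                )
            d[f.name] = v
        return d


def _load_resources(config: RunConfig):
    if config.lexicon_path is not None:
        if not Path(config.lexicon_path).exists():
            raise FileNotFoundError(config.lexicon_path)
        lexicon = load_lexicon(config.lexicon_path, masked=config.mask)
    else:
        lexicon = fixture_lexicon(masked=config.mask)
    if config.gazetteer_path is not None:
        gazetteer = load_gazetteer(
            config.gazetteer_path, config.postal_path, config.phone_path
        )
    else:
        gazetteer = default_gazetteer()
    population = (
        load_population(config.population_path)
        if config.population_path is not None
        else default_population()
    )
    return lexicon, gazetteer, population


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "radsent_version": __version__,
        "config": config.to_manifest(),
        "stages": {},
        "status": "RUNNING",
    }
    stage = "setup"
    try:
        # --- corpus -------------------------------------------------------
        if config.corpus_path is not None:
            stage = "read_corpus"
            tweets = read_corpus(config.corpus_path, config.window)
        else:
            stage = "simulate"
            syn = config.synthetic if config.synthetic is not None else SyntheticConfig()
            tweets, truth = generate_corpus(syn)
            write_corpus(tweets, out / "corpus.jsonl")
            truth.to_csv(out / "truth.csv", index=False)
        manifest["stages"]["corpus"] = {"n_tweets": len(tweets)}

        # --- grouping -----------------------------------------------------
        stage = "grouping"
        grouped = group_corpus(tweets, config.keywords)
        manifest["stages"]["grouping"] = {
            "n_filtered": int(len(grouped)),
            "n_target": int((grouped["group"] == "TARGET").sum()),
            "n_rt_group": int((grouped["group"] == "RT_GROUP").sum()),
        }

        # --- sentiment + geoparse (single tokenize pass) ------------------
        stage = "sentiment"
        lexicon, gazetteer, population = _load_resources(config)
        tokenizer = DictionaryTokenizer.from_resources(
            lexicon, gazetteer_words=gazetteer.vocabulary()
        )
        t_pn, w_c, prefectures = [], [], []
        for text in grouped["clean_text"]:
            tokens = tokenizer(preprocess(text))
            score, count = score_tokens(tokens, lexicon, config.count_all_tokens)
            prefs = resolve_prefectures(text, tokens, gazetteer)
            t_pn.append(score)
            w_c.append(count)
            prefectures.append(";".join(sorted(p.value for p in prefs)))
        scored = grouped.assign(t_pn=t_pn, w_c=w_c, prefectures=prefectures)
        scored_out = scored.copy()
        scored_out["timestamp"] = scored_out["timestamp"].map(lambda t: t.isoformat())
        scored_out.to_csv(out / "scored.csv", index=False)
        manifest["stages"]["sentiment"] = {
            "n_scored": int(len(scored)),
            "n_zero_wc": int((scored["w_c"] == 0).sum()),
        }
        manifest["stages"]["geoparse"] = {
            "n_geolocated": int((scored["prefectures"] != "").sum()),
        }

        # --- aggregation --------------------------------------------------
        stage = "aggregate"
        daily = bucketize(scored, Granularity.DAY, window=config.window)
        daily.to_csv(out / "daily_all.csv", index=False)
        cumulative_series(daily).to_csv(out / "daily_cumulative.csv", index=False)
        daily_group = bucketize(scored, Granularity.DAY, by=("group",), window=config.window)
        daily_group.to_csv(out / "daily_by_group.csv", index=False)
        weekly_group = bucketize(scored, Granularity.WEEK, by=("group",), window=config.window)
        weekly_group.to_csv(out / "weekly_by_group.csv", index=False)

        stage = "f_tests"
        ftests = weekly_f_series(
            scored, alpha=config.alpha, mode=config.f_test_mode, window=config.window
        )
        ftests.to_csv(out / "weekly_f_tests.csv", index=False)

        stage = "regional"
        geo = scored[scored["prefectures"] != ""].copy()
        geo["is_fukushima"] = geo["prefectures"].str.contains(Prefecture.FUKUSHIMA.value)
        ratios = fukushima_weekly_ratios(geo, window=config.window)
        ratios.to_csv(out / "weekly_fukushima_ratios.csv", index=False)

        counts: dict[str, int] = {}
        for prefs in geo["prefectures"]:
            for name in prefs.split(";"):
                counts[name] = counts.get(name, 0) + 1
        regional_rows = []
        for pref in Prefecture:
            n_tweets = counts.get(pref.value, 0)
            pop = population.get(pref)
            regional_rows.append(
                {
                    "prefecture": pref.value,
                    "n_tweets": n_tweets,
                    "population": pop if pop is not None else "",
                    "tweets_per_1000": per_capita_rate(n_tweets, pop)
                    if pop is not None
                    else "",
                }
            )
        pd.DataFrame(regional_rows).to_csv(out / "regional_per_capita.csv", index=False)
        manifest["stages"]["regional"] = {"n_geolocated_tweets": int(len(geo))}

        stage = "trends"
        trend_rows = []
        for grp, sub in weekly_group.groupby("group"):
            t = sub["bucket"].str.removeprefix("W").astype(int)
            if t.nunique() >= 2:
                fit = fit_trend(t, sub["mean_tpn"])
                trend_rows.append(
                    {
                        "series": f"weekly_mean_{grp}",
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "stderr_slope": fit.stderr_slope,
                        "n_points": fit.n_points,
                    }
                )
        valid = ratios.dropna(subset=["count_ratio"])
        if len(valid) >= 2:
            t = valid["bucket"].str.removeprefix("W").astype(int)
            fit = fit_trend(t, valid["count_ratio"])
            trend_rows.append(
                {
                    "series": "weekly_fukushima_count_ratio",
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "stderr_slope": fit.stderr_slope,
                    "n_points": fit.n_points,
                }
            )
        pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)

        manifest["status"] = "OK"
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
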