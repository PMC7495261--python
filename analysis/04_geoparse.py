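#!/usr/bin/env python
"""Resolve each scored tweet to prefectures and build the per-capita table.

Reads scratch/analysis/scored.csv (from 03), extracts regional identifiers
(proper-noun/region tokens, postal codes, phone numbers), resolves them
through the offline gazetteer, and writes the prefecture breakdown with
tweets per 1000 residents (2011-10-01 populations).
"""

from pathlib import Path

import pandas as pd

from radsent.geoparse import (
    Prefecture,
    default_gazetteer,
    default_population,
    per_capita_rate,
    resolve_prefectures,
)
from radsent.sentiment import DictionaryTokenizer, fixture_lexicon

WORKDIR = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    scored = pd.read_csv(WORKDIR / "scored.csv", keep_default_na=False)
    gazetteer = default_gazetteer()
    population = default_population()
    tokenizer = DictionaryTokenizer.from_resources(
        fixture_lexicon(), gazetteer_words=gazetteer.vocabulary()
    )

    prefs_col = []
    counts: dict[str, int] = {}
    for text in scored["text"]:
        prefs = resolve_prefectures(text, tokenizer(text), gazetteer)
        prefs_col.append(";".join(sorted(p.value for p in prefs)))
        for p in prefs:
            counts[p.value] = counts.get(p.value, 0) + 1
    scored["prefectures"] = prefs_col
    scored.to_csv(WORKDIR / "geoparsed.csv", index=False)

    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for pref in Prefecture:
        n = counts.get(pref.value, 0)
        pop = population.get(pref)
        rows.append(
            {
                "prefecture": pref.value,
                "n_tweets": n,
                "population": pop if pop else "",
                "tweets_per_1000": per_capita_rate(n, pop) if pop else "",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "prefecture_breakdown.csv", index=False)

    n_geo = int((scored["prefectures"] != "").sum())
    top = table[table["n_tweets"] > 0].nlargest(5, "n_tweets")
    print(f"{n_geo} of {len(scored)} tweets carry a resolvable regional identifier")
    print("top prefectures by tweet count:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
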