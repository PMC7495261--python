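#!/usr/bin/env python
"""Score every grouped tweet: T_pn = ΣW_pn / W_c over its dictionary words.

Reads scratch/analysis/grouped.csv (from 02), tokenizes each cleaned text
with the builtin dictionary tokenizer, and scores it against the packaged
semantic-orientation lexicon (query keywords masked to 0).  Writes the
scored records, plus daily mean and cumulative series to results/.
"""

from pathlib import Path

import pandas as pd

from radsent.aggregate import Granularity, bucketize, cumulative_series
from radsent.corpus_io import JST
from radsent.geoparse import default_gazetteer
from radsent.sentiment import DictionaryTokenizer, fixture_lexicon, preprocess, score_tokens

WORKDIR = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    grouped = pd.read_csv(WORKDIR / "grouped.csv", keep_default_na=False)
    grouped["timestamp"] = pd.to_datetime(grouped["timestamp"]).dt.tz_convert(JST)

    lexicon = fixture_lexicon()
    tokenizer = DictionaryTokenizer.from_resources(
        lexicon, gazetteer_words=default_gazetteer().vocabulary()
    )
    scores, counts = [], []
    for text in grouped["clean_text"]:
        t_pn, w_c = score_tokens(tokenizer(preprocess(text)), lexicon)
        scores.append(t_pn)
        counts.append(w_c)
    scored = grouped.assign(t_pn=scores, w_c=counts)
    out = scored.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(WORKDIR / "scored.csv", index=False)

    RESULTS.mkdir(parents=True, exist_ok=True)
    daily = bucketize(scored, Granularity.DAY, by=("group",))
    daily.to_csv(RESULTS / "daily_mean_by_group.csv", index=False)
    cumulative = cumulative_series(bucketize(scored, Granularity.DAY))
    cumulative.to_csv(RESULTS / "daily_cumulative.csv", index=False)

    overall = scored["t_pn"].mean()
    by_group = scored.groupby("group")["t_pn"].mean()
    print(f"scored {len(scored)} tweets; overall mean T_pn = {overall:.4f}")
    print(by_group.to_string())
    print(f"cumulative sum ends at {cumulative['cum_sum_tpn'].iloc[-1]:.1f}")


if __name__ == "__main__":
    main()
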