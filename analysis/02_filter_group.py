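#!/usr/bin/env python
"""Keyword-filter the corpus and partition it into target and RT groups.

Reads scratch/analysis/corpus.jsonl (from 01), applies the corpus-definition
rules — keyword containment, bot-handle and RT/QT-prefix detection, inline-RT
truncation — and writes the grouped records plus a small breakdown table.
"""

from pathlib import Path

import pandas as pd

from radsent.corpus_io import read_corpus
from radsent.grouping import group_corpus

WORKDIR = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    tweets = read_corpus(WORKDIR / "corpus.jsonl")
    grouped = group_corpus(tweets)

    out = grouped.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(WORKDIR / "grouped.csv", index=False)

    RESULTS.mkdir(parents=True, exist_ok=True)
    breakdown = (
        grouped.groupby(["group", "rt_reason"]).size().rename("n").reset_index()
    )
    breakdown.to_csv(RESULTS / "group_breakdown.csv", index=False)

    n = len(grouped)
    n_rt = int((grouped["group"] == "RT_GROUP").sum())
    print(f"{len(tweets)} tweets read; {n} pass the keyword filter")
    print(f"  target group: {n - n_rt}  |  RT group: {n_rt} ({100 * n_rt / n:.1f}%)")
    print(breakdown.to_string(index=False))


if __name__ == "__main__":
    main()
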