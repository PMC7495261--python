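"""Tweet records, the study window, and corpus/table input-output.

The corpus is a line-delimited record stream, one JSON object per line with
keys ``tweet_id``, ``timestamp``, ``user_id``, ``text``.  A four-column
tab-separated alternative (same field order) is accepted.  All temporal logic
runs in Japan Standard Time (UTC+9): the analysis window is anchored at the
2011-03-11 earthquake in JST, and timestamps carrying other offsets are
converted on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Japan Standard Time; every bucket boundary in the pipeline lives here.
JST = timezone(timedelta(hours=9), name="JST")


@dataclass(frozen=True)
class Tweet:
    """One timestamped, authored text record — the pipeline's atomic unit."""

    tweet_id: str
    timestamp: datetime  # timezone-aware; normalised to JST on construction paths
    user_id: str
    text: str

    def to_record(self) -> dict:
        return {
            "tweet_id": self.tweet_id,
            "timestamp": self.timestamp.astimezone(JST).isoformat(),
            "user_id": self.user_id,
            "text": self.text,
        }


@dataclass(frozen=True)
class StudyWindow:
    """One year from the earthquake: 2011-03-11 00:00 to 2012-03-10 23:59:59 JST.

    Both endpoints are inclusive at one-second resolution; sub-second parts of
    a timestamp are truncated before the membership test, which makes the
    window equivalent to the half-open interval [start, start + 365 days).
    """

    start: datetime = field(default_factory=lambda: datetime(2011, 3, 11, 0, 0, 0, tzinfo=JST))
    end: datetime = field(default_factory=lambda: datetime(2012, 3, 10, 23, 59, 59, tzinfo=JST))

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("study window start must precede end")

    def contains(self, ts: datetime) -> bool:
        if ts.tzinfo is None:
            raise ValueError("naive timestamps are ambiguous; attach an offset")
        ts = ts.astimezone(JST).replace(microsecond=0)
        return self.start <= ts <= self.end

    def day_index(self, ts: datetime) -> int:
        """Whole days elapsed since the window start (0 on day one)."""
        return (ts.astimezone(JST) - self.start) // timedelta(days=1)

    def week_index(self, ts: datetime) -> int:
        """7-day half-open weeks anchored at the window start (not ISO weeks)."""
        return self.day_index(ts) // 7

    @property
    def n_days(self) -> int:
        return (self.end.date() - self.start.date()).days + 1


DEFAULT_WINDOW = StudyWindow()


def parse_timestamp(raw) -> datetime:
    """ISO-8601 with offset, or epoch seconds (assumed UTC), to JST."""
    if isinstance(raw, (int, float)) or (isinstance(raw, str) and raw.strip().lstrip("-").isdigit()):
        return datetime.fromtimestamp(float(raw), tz=timezone.utc).astimezone(JST)
    ts = datetime.fromisoformat(str(raw).strip())
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {raw!r} carries no UTC offset")
    return ts.astimezone(JST)


def _parse_line(line: str) -> Tweet:
    line = line.strip()
    if line.startswith("{"):
        rec = json.loads(line)
        ts = parse_timestamp(rec["timestamp"])
        return Tweet(str(rec["tweet_id"]), ts, str(rec["user_id"]), str(rec["text"]))
    parts = line.split("\t")
    if len(parts) != 4:
        raise ValueError("expected JSON object or 4 tab-separated fields")
    return Tweet(parts[0], parse_timestamp(parts[1]), parts[2], parts[3])


def read_corpus(path: str | Path, window: StudyWindow = DEFAULT_WINDOW) -> list[Tweet]:
    """Read the corpus, keeping in-window records in timestamp order.

    Unparseable lines and timestamps are skipped with a logged count rather
    than aborting the run; out-of-window records are counted and dropped.
    Duplicate tweet ids keep the first occurrence.  A missing file is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tweets: list[Tweet] = []
    seen: set[str] = set()
    n_bad = n_outside = n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                tw = _parse_line(line)
            except (ValueError, KeyError, json.JSONDecodeError):
                n_bad += 1
                continue
            if not window.contains(tw.timestamp):
                n_outside += 1
                continue
            if tw.tweet_id in seen:
                n_dup += 1
                continue
            seen.add(tw.tweet_id)
            tweets.append(tw)
    if n_bad or n_outside or n_dup:
        logger.warning(
            "read_corpus(%s): skipped %d unparseable, %d outside window, %d duplicate ids",
            path, n_bad, n_outside, n_dup,
        )
    tweets.sort(key=lambda t: t.timestamp)
    return tweets


def write_corpus(tweets: Iterable[Tweet], path: str | Path) -> None:
    """Write tweets as JSON lines (UTF-8, one object per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tw in tweets:
            fh.write(json.dumps(tw.to_record(), ensure_ascii=False) + "\n")


def write_table(rows, path: str | Path) -> None:
    """Write homogeneous records (or a DataFrame) as a UTF-8 CSV with header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def corpus_frame(tweets: Sequence[Tweet]) -> pd.DataFrame:
    """Tweets as a DataFrame (timestamp kept timezone-aware, JST)."""
    return pd.DataFrame(
        {
            "tweet_id": [t.tweet_id for t in tweets],
            "timestamp": pd.DatetimeIndex([t.timestamp for t in tweets]).tz_convert(JST)
            if tweets
            else pd.DatetimeIndex([], tz=JST),
            "user_id": [t.user_id for t in tweets],
            "text": [t.text for t in tweets],
        }
    )
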