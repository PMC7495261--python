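"""Corpus-definition rules: keyword filter, bot/RT detection, inline-RT cut.

Tweets that pass the radiation keyword filter are partitioned into a *target
group* (taken to express the original poster's own feeling) and an *RT group*
pooling automated "bot" accounts with retweets/quote-tweets.  Target-group
text is additionally truncated at an inline ``RT @`` marker so that quoted
material does not contaminate the poster's own words.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .corpus_io import Tweet

#: Radiation / radioactivity / radioactive substances.
DEFAULT_KEYWORDS = frozenset({"放射線", "放射能", "放射性物質"})


class Group(str, Enum):
    TARGET = "TARGET"
    RT_GROUP = "RT_GROUP"


class RtReason(str, Enum):
    BOT_ACCOUNT = "BOT_ACCOUNT"
    STARTS_WITH_RT = "STARTS_WITH_RT"
    STARTS_WITH_QT = "STARTS_WITH_QT"


@dataclass(frozen=True)
class GroupLabel:
    group: Group
    rt_reason: Optional[RtReason] = None

    def __post_init__(self) -> None:
        if (self.group is Group.RT_GROUP) != (self.rt_reason is not None):
            raise ValueError("rt_reason must be present exactly when group is RT_GROUP")


# 2011-era client conventions: leading whitespace tolerated, full-width colon
# accepted after the RT/QT marker.
_RT_PREFIX = re.compile(r"^\s*(RT|QT)[\s@:：]", re.IGNORECASE)
_INLINE_RT = re.compile(r"(RT|QT)\s*@", re.IGNORECASE)


def keyword_filter(text: str, keywords: Iterable[str] = DEFAULT_KEYWORDS) -> bool:
    """True iff the text contains any keyword as a substring.

    Japanese carries no word boundaries, so substring containment is the only
    well-defined reading.  NFKC normalisation makes full-width variants match.
    """
    text = unicodedata.normalize("NFKC", text)
    return any(k in text for k in keywords)


def classify_group(user_id: str, text: str) -> GroupLabel:
    """Pure function of (handle, text): bot rule first, then RT/QT prefix.

    Bot accounts are handles that begin or end with "bot", case-insensitively
    (a literal prefix/suffix test, not substring: "robotics_fan" is not a bot,
    "botanist" is — a documented false-positive source of the heuristic).
    """
    handle = user_id.lower()
    if handle.startswith("bot") or handle.endswith("bot"):
        return GroupLabel(Group.RT_GROUP, RtReason.BOT_ACCOUNT)
    m = _RT_PREFIX.match(text)
    if m:
        reason = RtReason.STARTS_WITH_RT if m.group(1).upper() == "RT" else RtReason.STARTS_WITH_QT
        return GroupLabel(Group.RT_GROUP, reason)
    return GroupLabel(Group.TARGET)


def truncate_inline_rt(text: str) -> str:
    """Cut the text before the first mid-text ``RT @`` / ``QT @`` marker.

    Applied to target-group tweets only, so that reposted material appended
    after the poster's own comment is not scored as their sentiment.
    Idempotent; text without a marker is returned unchanged.
    """
    m = _INLINE_RT.search(text)
    return text[: m.start()] if m else text


def group_corpus(
    tweets: Iterable[Tweet], keywords: Iterable[str] = DEFAULT_KEYWORDS
) -> pd.DataFrame:
    """Filter on the full text, label each survivor, and derive clean_text.

    Keyword matching runs on the untruncated text (a tweet whose only keyword
    sits in a quoted tail still counts as being about radiation); truncation
    is then applied to target-group tweets before scoring.
    """
    rows = []
    for tw in tweets:
        if not keyword_filter(tw.text, keywords):
            continue
        label = classify_group(tw.user_id, tw.text)
        clean = truncate_inline_rt(tw.text) if label.group is Group.TARGET else tw.text
        rows.append(
            {
                "tweet_id": tw.tweet_id,
                "timestamp": tw.timestamp,
                "user_id": tw.user_id,
                "text": tw.text,
                "group": label.group.value,
                "rt_reason": label.rt_reason.value if label.rt_reason else "",
                "clean_text": clean,
            }
        )
    cols = ["tweet_id", "timestamp", "user_id", "text", "group", "rt_reason", "clean_text"]
    return pd.DataFrame(rows, columns=cols)
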