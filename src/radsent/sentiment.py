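"""Semantic-orientation lexicon, tokenizer contract, and tweet scoring.

Each dictionary word carries a semantic-orientation value in [−1, 1]
(negative impression … positive impression).  A tweet's score is

    T_pn = (Σ W_pn) / W_c

the mean of its words' values over the tweet's word count W_c.  The three
radiation query keywords (and the 放射性 stem) are intrinsically negative in
the dictionary; because they appear in every tweet by construction of the
corpus, they are *masked* — scored as 0 points while still counting toward
W_c — so the statistic measures feeling about radiation rather than the
query terms themselves.  Out-of-vocabulary words likewise score 0.

Tokenization is a pluggable contract: any callable mapping text to an
ordered list of (surface, base_form, pos, pos_sub1, pos_sub2) tuples.  A
morphological analyzer such as MeCab fits the contract; the package ships a
dictionary-driven longest-match tokenizer over the lexicon ∪ gazetteer
vocabulary so the whole pipeline runs without an external analyzer.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple, Optional

logger = logging.getLogger(__name__)

#: Query keywords plus the 放射性 stem (放射性物質 segments as 放射性+物質
#: under standard morphological analysis), all forced to 0 points.
DEFAULT_MASK = frozenset({"放射線", "放射能", "放射性", "放射性物質"})

SYMBOL_POS = "記号"
WHITESPACE_SUB = "空白"
REGION_POS = ("名詞", "固有名詞", "地域")


class Token(NamedTuple):
    surface: str
    base: str
    pos: str
    pos_sub1: str
    pos_sub2: str


Tokenizer = Callable[[str], list[Token]]


@dataclass(frozen=True)
class Lexicon:
    """word → semantic-orientation value in [−1, 1], plus the masked set."""

    entries: Mapping[str, float]
    masked: frozenset[str] = DEFAULT_MASK

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty lexicon")

    def value(self, base_form: str) -> float:
        """0 for masked and out-of-vocabulary words, else the dictionary value."""
        if base_form in self.masked:
            return 0.0
        return self.entries.get(base_form, 0.0)


def word_value(lexicon: Lexicon, base_form: str) -> float:
    return lexicon.value(base_form)


def load_lexicon(path: str | Path, masked: Iterable[str] = DEFAULT_MASK) -> Lexicon:
    """Parse a lexicon in ``surface:reading:pos:value`` dialect or 2-column TSV.

    Malformed lines and unparseable values are skipped with a logged count;
    values outside [−1, 1] are clipped with a warning; a duplicated word keeps
    its first value.  An empty result is fatal.
    """
    entries: dict[str, float] = {}
    n_bad = n_dup = n_clip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                parts = line.split("\t")
                word, raw = parts[0], parts[-1]
            else:
                parts = line.rsplit(":", 3)
                if len(parts) != 4:
                    n_bad += 1
                    continue
                word, raw = parts[0], parts[3]
            try:
                value = float(raw)
            except ValueError:
                n_bad += 1
                continue
            if not -1.0 <= value <= 1.0:
                value = max(-1.0, min(1.0, value))
                n_clip += 1
            if word in entries:
                n_dup += 1
                continue
            entries[word] = value
    if n_bad or n_dup or n_clip:
        logger.warning(
            "load_lexicon(%s): %d malformed, %d duplicate (first kept), %d clipped",
            path, n_bad, n_dup, n_clip,
        )
    if not entries:
        raise ValueError(f"lexicon {path} contains no parseable entries")
    return Lexicon(entries=entries, masked=frozenset(masked))


def fixture_lexicon(masked: Iterable[str] = DEFAULT_MASK) -> Lexicon:
    """The packaged ~50-word test lexicon (value grid + radiation terms)."""
    with resources.as_file(resources.files("radsent.data") / "pn_fixture.dic") as p:
        return load_lexicon(p, masked=masked)


# --- text preprocessing -----------------------------------------------------

_URL = re.compile(r"https?://\S+")
_MENTION = re.compile(r"[@＠][A-Za-z0-9_]+")
_HASHMARK = re.compile(r"[#＃]")


def preprocess(text: str) -> str:
    """NFKC-normalise and strip URLs, @mentions and hashtag markers.

    None of these are dictionary words; left in place they would inflate W_c
    and dilute every score.  The hashtag's word itself is kept — only the
    marker is removed.
    """
    text = unicodedata.normalize("NFKC", text)
    text = _URL.sub(" ", text)
    text = _MENTION.sub(" ", text)
    return _HASHMARK.sub("", text)


# --- builtin tokenizer ------------------------------------------------------


class DictionaryTokenizer:
    """Greedy longest-match tokenizer over a fixed vocabulary.

    Stands in for a morphological analyzer in environments without one: at
    each position the longest vocabulary word wins; characters outside the
    vocabulary are grouped into maximal runs of the same class (word-like /
    punctuation / whitespace).  The concatenation of surfaces reconstructs
    the input exactly.
    """

    def __init__(self, vocabulary: Mapping[str, tuple[str, str, str]]):
        # vocabulary: surface -> (pos, pos_sub1, pos_sub2); base form == surface
        self._vocab = dict(vocabulary)
        self._maxlen = max((len(w) for w in self._vocab), default=1)

    @classmethod
    def from_resources(
        cls,
        lexicon: Lexicon,
        gazetteer_words: Iterable[str] = (),
        extra_words: Iterable[str] = (),
    ) -> "DictionaryTokenizer":
        vocab: dict[str, tuple[str, str, str]] = {}
        for w in lexicon.entries:
            vocab[w] = ("名詞", "一般", "")
        for w in lexicon.masked:
            vocab.setdefault(w, ("名詞", "一般", ""))
        for w in extra_words:
            vocab.setdefault(w, ("名詞", "一般", ""))
        for w in gazetteer_words:
            vocab[w] = REGION_POS  # region words tag as proper-noun/region
        return cls(vocab)

    @staticmethod
    def _char_class(ch: str) -> str:
        if ch.isspace():
            return "space"
        cat = unicodedata.category(ch)
        if cat[0] in ("P", "S") or cat in ("Cc", "Cf"):
            return "punct"
        return "word"

    def __call__(self, text: str) -> list[Token]:
        tokens: list[Token] = []
        run: list[str] = []
        run_class = ""

        def flush() -> None:
            nonlocal run, run_class
            if run:
                s = "".join(run)
                if run_class == "space":
                    tokens.append(Token(s, s, SYMBOL_POS, WHITESPACE_SUB, ""))
                elif run_class == "punct":
                    tokens.append(Token(s, s, SYMBOL_POS, "一般", ""))
                else:
                    tokens.append(Token(s, s, "名詞", "一般", ""))
                run, run_class = [], ""

        i, n = 0, len(text)
        while i < n:
            match = None
            for length in range(min(self._maxlen, n - i), 0, -1):
                cand = text[i : i + length]
                if cand in self._vocab:
                    match = cand
                    break
            if match is not None:
                flush()
                pos = self._vocab[match]
                tokens.append(Token(match, match, *pos))
                i += len(match)
            else:
                cls_ = self._char_class(text[i])
                if cls_ != run_class:
                    flush()
                    run_class = cls_
                run.append(text[i])
                i += 1
        flush()
        return tokens


def default_tokenizer(lexicon: Optional[Lexicon] = None) -> DictionaryTokenizer:
    """Builtin tokenizer over the fixture lexicon ∪ packaged gazetteer."""
    from .geoparse import default_gazetteer  # local import: avoid cycle at load

    lex = lexicon if lexicon is not None else fixture_lexicon()
    gaz = default_gazetteer()
    return DictionaryTokenizer.from_resources(lex, gazetteer_words=gaz.vocabulary())


# --- scoring ----------------------------------------------------------------


def is_content_token(tok: Token) -> bool:
    return tok.pos != SYMBOL_POS


def score_tokens(
    tokens: Iterable[Token], lexicon: Lexicon, count_all_tokens: bool = False
) -> tuple[float, int]:
    """T_pn and W_c from an already-tokenized text.

    W_c counts content tokens (punctuation, symbols and whitespace are not
    words); set ``count_all_tokens`` to include them for sensitivity analysis.
    Masked words contribute 0 to the numerator but still count toward W_c.
    An empty tweet scores (0, 0) by convention.
    """
    total = 0.0
    w_c = 0
    for tok in tokens:
        if not count_all_tokens and not is_content_token(tok):
            continue
        w_c += 1
        total += lexicon.value(tok.base)
    if w_c == 0:
        return 0.0, 0
    return total / w_c, w_c


def score_tweet(
    clean_text: str,
    tokenizer: Tokenizer,
    lexicon: Lexicon,
    count_all_tokens: bool = False,
) -> tuple[float, int]:
    """Preprocess, tokenize, and compute (T_pn, W_c) for one tweet."""
    return score_tokens(tokenizer(preprocess(clean_text)), lexicon, count_all_tokens)
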