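"""Lexicon parsing, the builtin tokenizer, and T_pn scoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsent.sentiment import (
    DEFAULT_MASK,
    DictionaryTokenizer,
    Lexicon,
    Token,
    fixture_lexicon,
    load_lexicon,
    preprocess,
    score_tokens,
    score_tweet,
    word_value,
)


# --- lexicon ----------------------------------------------------------------

def test_load_takamura_dialect(tmp_path):
    path = tmp_path / "pn.dic"
    path.write_text("優れる:すぐれる:動詞:1\n良い:よい:形容詞:0.8\n", encoding="utf-8")
    lex = load_lexicon(path)
    assert lex.entries["優れる"] == 1.0
    assert lex.entries["良い"] == 0.8


def test_load_tsv_dialect_and_masking(tmp_path):
    path = tmp_path / "pn.tsv"
    path.write_text("放射能\t-0.598318\n良い\t0.8\n", encoding="utf-8")
    lex = load_lexicon(path)
    assert lex.entries["放射能"] == -0.598318  # raw dictionary value is kept...
    assert lex.value("放射能") == 0.0          # ...but masked to 0 points at lookup
    assert lex.value("良い") == 0.8


def test_load_lexicon_skips_bad_keeps_first_clips(tmp_path, caplog):
    path = tmp_path / "pn.dic"
    path.write_text(
        "良い:よい:形容詞:0.8\n良い:よい:形容詞:0.1\nmalformed line\n"
        "大きい:おおきい:形容詞:not_a_number\n過大:かだい:名詞:1.5\n",
        encoding="utf-8",
    )
    with caplog.at_level("WARNING"):
        lex = load_lexicon(path)
    assert lex.entries["良い"] == 0.8     # duplicate keeps first
    assert lex.entries["過大"] == 1.0     # clipped into [-1, 1]
    assert "大きい" not in lex.entries


def test_empty_lexicon_is_fatal(tmp_path):
    path = tmp_path / "pn.dic"
    path.write_text("garbage\n", encoding="utf-8")
    with pytest.raises(ValueError):
        load_lexicon(path)


def test_word_value_masked_oov_and_hit():
    lex = Lexicon(entries={"良い": 0.8, "放射線": -0.560393})
    assert word_value(lex, "放射線") == 0.0   # masked query keyword
    assert word_value(lex, "グーグル") == 0.0  # out of vocabulary
    assert word_value(lex, "良い") == 0.8


# --- builtin tokenizer ------------------------------------------------------

def test_tokenizer_longest_match(tokenizer):
    tokens = tokenizer("放射性物質")
    assert [t.surface for t in tokens] == ["放射性物質"]  # not 放射性 + 物質


def test_tokenizer_region_pos(tokenizer):
    tokens = tokenizer("福島市東京")
    assert [(t.surface, t.pos_sub2) for t in tokens] == [("福島市", "地域"), ("東京", "地域")]


@given(st.text(max_size=60))
@settings(derandomize=True, max_examples=200)
def test_tokenizer_reconstructs_input(tokenizer, text):
    tokens = tokenizer(text)
    assert "".join(t.surface for t in tokens) == text


# --- scoring ----------------------------------------------------------------

def _toks(*words):
    return [Token(w, w, "名詞", "一般", "") for w in words]


def test_score_examples_hand_summed():
    lex = Lexicon(entries={"a": 0.6, "b": -0.2, "c": 0.5})
    # {0.6, -0.2, OOV 0} over W_c=3 -> 0.4/3
    t_pn, w_c = score_tokens(_toks("a", "b", "x"), lex)
    assert w_c == 3 and t_pn == pytest.approx(0.4 / 3, abs=1e-12)
    # single token identity
    assert score_tokens(_toks("c"), lex) == (0.5, 1)
    # all OOV -> zero numerator, nonzero W_c
    assert score_tokens(_toks("x", "y", "z"), lex) == (0.0, 3)


def test_masked_only_tweet_scores_zero(tokenizer, lexicon):
    t_pn, w_c = score_tweet("放射能", tokenizer, lexicon)
    assert (t_pn, w_c) == (0.0, 1)  # masked word scores 0 but still counts


def test_empty_text_scores_zero(tokenizer, lexicon):
    assert score_tweet("", tokenizer, lexicon) == (0.0, 0)
    assert score_tweet("。、！", tokenizer, lexicon) == (0.0, 0)  # symbols only


def test_punctuation_excluded_unless_requested(lexicon):
    toks = _toks("放射能") + [Token("。", "。", "記号", "一般", "")]
    assert score_tokens(toks, lexicon)[1] == 1
    assert score_tokens(toks, lexicon, count_all_tokens=True)[1] == 2


def test_urls_mentions_hashmarks_stripped(tokenizer, lexicon):
    plain = score_tweet("放射能 怖い", tokenizer, lexicon)
    noisy = score_tweet("放射能 怖い http://t.co/abc @friend #話題", tokenizer, lexicon)
    # "話題" survives (only the # marker is stripped) as one OOV token
    assert noisy[1] == plain[1] + 1
    assert noisy[0] == pytest.approx(plain[0] * plain[1] / noisy[1], abs=1e-12)


@st.composite
def token_lists(draw):
    lex = draw(
        st.dictionaries(
            st.text(alphabet="あいうえおかきくけこ", min_size=1, max_size=3),
            st.floats(min_value=-1, max_value=1, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    words = draw(
        st.lists(
            st.one_of(st.sampled_from(sorted(lex)), st.just("未知語"), st.just("放射線")),
            max_size=30,
        )
    )
    return Lexicon(entries=lex), words


@given(token_lists())
@settings(derandomize=True, max_examples=300)
def test_score_matches_bruteforce_oracle_and_is_bounded(case):
    lexicon, words = case
    t_pn, w_c = score_tokens(_toks(*words), lexicon)
    # independent brute-force loop
    total, count = 0.0, 0
    for w in words:
        count += 1
        if w in lexicon.masked:
            continue
        total += lexicon.entries.get(w, 0.0)
    if count == 0:
        assert (t_pn, w_c) == (0.0, 0)
    else:
        assert w_c == count
        assert t_pn == pytest.approx(total / count, abs=1e-12)
    assert -1.0 <= t_pn <= 1.0


@given(token_lists(), st.randoms(use_true_random=False))
@settings(derandomize=True, max_examples=100)
def test_score_is_permutation_invariant(case, rnd):
    lexicon, words = case
    shuffled = list(words)
    rnd.shuffle(shuffled)
    assert score_tokens(_toks(*words), lexicon)[0] == pytest.approx(
        score_tokens(_toks(*shuffled), lexicon)[0], abs=1e-12
    )


def test_mask_neutrality(lexicon):
    """Adding a masked word never moves the numerator (it only grows W_c)."""
    base_words = ["良い", "怖い"]
    t0, w0 = score_tokens(_toks(*base_words), lexicon)
    t1, w1 = score_tokens(_toks(*base_words, "放射能"), lexicon)
    assert w1 == w0 + 1
    assert t1 * w1 == pytest.approx(t0 * w0, abs=1e-12)


def test_fixture_lexicon_values_within_bounds(lexicon):
    assert all(-1.0 <= v <= 1.0 for v in lexicon.entries.values())
    assert lexicon.entries["放射能"] == -0.598318
    assert lexicon.entries["放射線"] == -0.560393
    assert lexicon.entries["放射性"] == -0.178744
    assert DEFAULT_MASK <= set(lexicon.entries) | {"放射性物質"}
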