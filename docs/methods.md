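# Methods

This note records what the package computes, the assumptions behind each
stage, the defaults and why they are what they are, and what the synthetic
evaluation does and does not establish.

## Corpus definition

The unit of analysis is a tweet: id, timestamp, author handle, text.  All
temporal logic runs in JST (UTC+9).  The study window is the year from
2011-03-11 00:00:00 to 2012-03-10 23:59:59 JST, both endpoints inclusive at
one-second resolution (sub-second parts are truncated, making the window
equivalent to the half-open `[start, start + 365 days)`).  Timestamps with
other offsets are converted; epoch-second timestamps are interpreted as UTC.
Records outside the window, unparseable lines and duplicate ids are counted
and logged, never silently dropped; duplicates keep their first occurrence
(the platform does not reuse ids, so later occurrences are re-deliveries).

A tweet enters the corpus if its raw text contains 放射線, 放射能 or
放射性物質 as a substring — Japanese has no word boundaries, so substring
containment is the only well-defined keyword test.  Text is NFKC-normalised
for this test so full-width variants match.

## Grouping

The corpus is partitioned once, by the first matching rule:

1. **Bot account** — the handle begins or ends with `bot`,
   case-insensitively.  This is a literal prefix/suffix rule, not a
   substring rule: `robotics_fan` is not a bot, while `botanist` is.  The
   false positives and negatives of this heuristic are inherited knowingly;
   broad ML bot detection is out of scope.
2. **Repost** — the text starts (after optional whitespace) with `RT` or
   `QT` followed by whitespace, `@`, `:` or the full-width `：` — the
   2011-era client conventions.
3. Otherwise **target group**: taken to express the poster's own feeling.

Bots and reposts together form the RT group.  Target-group text is
truncated at the first inline `RT @`/`QT @` marker before scoring, so
quoted material does not contaminate the poster's sentiment; RT-group text
is scored whole.  Keyword filtering deliberately runs on the *full* text,
before truncation: a tweet whose only keyword sits in the quoted tail is
still a tweet about radiation, and its (possibly empty) own comment is what
gets scored.  The truncation is idempotent and the partition conserves
counts (|target| + |RT| = |filtered|); both are property-tested.

## Scoring

T_pn = Σ W_pn / W_c over the tweet's tokens, using base forms.  Choices
that shape the number:

- **W_c counts content tokens.**  Punctuation, symbols and whitespace are
  not words and are excluded by default; `count_all_tokens=True` restores
  the all-morpheme count for sensitivity analysis (which convention the
  original analysts used is not determinable, so both exist).
- **Masked words score 0 but count toward W_c.**  They are scored as zero
  points, not deleted.  The default mask is {放射線, 放射能, 放射性,
  放射性物質}; 放射性 is included because 放射性物質 segments as
  放射性+物質 under standard morphological analysis, and its dictionary
  value (−0.178744) would otherwise leak the query term's polarity into
  every such tweet.  The mask is configurable.
- **OOV words score 0** and count toward W_c.  Consequently T_pn is always
  a mean of values in [−1, 1] and is itself bounded in [−1, 1] — asserted
  as a property test against a brute-force oracle.
- **Preprocessing**: NFKC normalisation, then URLs, @mentions and hashtag
  markers (the `#`, not the word) are stripped.  None of these are
  dictionary words; left in place they only inflate W_c.
- An empty or symbol-only tweet scores (0, 0); its zero is a *convention*,
  and aggregation treats empty cells as missing rather than zero so such
  conventions never fabricate a neutral observation.

Tokenization is a contract: any callable returning ordered
(surface, base, pos, pos_sub1, pos_sub2) tuples.  A morphological analyzer
(MeCab with the NEologd dictionary is the natural choice) plugs in
directly.  The packaged `DictionaryTokenizer` is a greedy longest-match
tokenizer over the lexicon ∪ gazetteer vocabulary: at each position the
longest vocabulary word wins, and characters outside the vocabulary are
grouped into maximal same-class runs (word-like runs count as OOV nouns,
punctuation/whitespace as symbols).  Its surfaces concatenate exactly back
to the input (property-tested).  It is a real tokenizer for vocabulary-
covered text, which the synthetic corpus guarantees; on arbitrary prose it
under-segments unknown kanji runs, which is the documented reason real-data
runs should plug in a morphological analyzer.

## Geoparsing

Three identifier channels, resolved offline and unioned:

- **Place names**: tokens tagged (noun, proper noun, region) looked up in
  the gazetteer.  The packaged table covers all 47 prefecture names (bare
  and suffixed), capital cities, the foreign nuclear-accident sites
  (チェルノブイリ, スリーマイル島 → OTHER) and generic address words
  (丁目, 番地 → OTHER) that cannot identify a prefecture.
- **Postal codes**: `〒?ddd-dddd` after NFKC, hyphen-variant tolerant,
  resolved by 3-digit prefix.  Phone-number spans are masked out first so a
  phone tail (`…-123-4567`) cannot masquerade as a postal code.
- **Phone numbers**: 9–11 digit spans starting with 0, hyphen-tolerant,
  resolved by longest-matching area-code prefix (so 0985/Miyazaki beats
  098/Okinawa).

A tweet naming several regions is assigned to all of them (multi-label);
the alternative first-match single-label convention would impose an
arbitrary order on an unordered set.  OTHER is reported only when an
identifier existed but nothing concrete resolved, so OTHER never co-occurs
with a real prefecture; a tweet with no identifier gets the empty set and
stays out of regional tables entirely.  Per-capita rates are
`round(count / population × 1000)` (half away from zero) using 2011-10-01
populations.  The packaged postal/phone tables carry one representative
(capital-city) prefix per prefecture — enough to exercise every lookup path
and resolve the synthetic stream completely; a full national table can be
dropped in as a same-shape TSV for real data.

## Aggregation

- Buckets: calendar-aligned days and minutes in JST; weeks are 7-day
  half-open intervals anchored at 2011-03-11 (ISO weeks would shift every
  boundary off the event).
- Weekly group means pool tweet-level scores over the week.  The weekly
  mean therefore equals the n-weighted mean of the daily means (tested to
  1e−12), not the unweighted mean of daily means.
- The weekly F test between target and RT scores defaults to one-way
  ANOVA — for two groups, exactly the squared pooled-t statistic, i.e. a
  test of mean divergence, which is what the weekly comparison is after.  A
  variance-ratio mode (two-sided p) is provided as the alternative reading.
  Weeks where either group has n < 2 yield a missing result, never a
  fabricated one.  No multiple-testing correction is applied across the 53
  weeks, matching the analysis this package reimplements; treat the
  per-week α = .05 flags as descriptive.
- Fukushima-vs-others: weekly count ratio n_F/n_O and the +1-shifted mean
  ratio (mean_F+1)/(mean_O+1).  The shift maps means into [0, 2] so the
  ratio of two non-negative quantities is interpretable; note the ratio
  itself is *not* bounded by 2 — it diverges as mean_O → −1 — so it is
  computed exactly and never clamped.
- Trend lines are ordinary least squares (scipy.stats.linregress), slope
  per bucket index, with the regression standard error reported; fits
  require ≥ 2 distinct abscissae and raise otherwise.

## Synthetic stream

The generator emulates the regimes the analysis assumes, with every
parameter recorded and recoverable:

| parameter | default | rationale |
|---|---|---|
| base_volume | 450/day | with decay, ≈100k tweets/year — a ~1:190 scale of the real stream, big enough for weekly inference at desk runtimes |
| volume_decay | 0.004/day | ≈4.3× volume drop over the year, matching a strong first-month concentration |
| events | Mar 12, Mar 15, Mar 23 spikes (1500/2000/1000, half-lives 2–3 d) | the reactor-explosion and dose-forecast news days dominate early volume |
| sentiment_base | −0.55 | the stream's overall tone is clearly negative |
| sentiment_slope | +0.0004/day | a mild positive drift (≈ +0.15 over the year) |
| bot_fraction / rt_fraction | 0.12 / 0.40 | RT group ≈52% of the corpus |
| bot_sentiment_offset | −0.10 | bots/reposts skew negative |
| geo_fraction | 0.33 | one third of tweets carry a regional identifier |
| fukushima share | logit −1.386 + 0.004/day | Fukushima's share of geolocated tweets rises from ≈0.20 toward ≈0.5 |
| noise_sd | 0.12 | per-tweet score dispersion; scores are means of ~a dozen word values, so tweet-level spread is well below the word-value range |

Daily counts are Poisson with the intensity above; per-tweet target scores
are Normal(μ_group(t), noise_sd) truncated to [−1, 1] via inverse-CDF
sampling.  Scores are **realized as tokens**: the fixture lexicon carries
one word per 0.05 grid value in [−1, 1], and a greedy chooser picks k = 12
scoring words whose grid values sum to the target (each slot takes the grid
value nearest the remaining deficit's mean, so the final residual on the
sum is at most half a grid step, ≤ 0.025, i.e. ≤ 0.002 on the mean).  The
keyword (masked), an optional region word (OOV) and the `RT` marker of
reposts all count toward W_c and are accounted for exactly.  Target means
beyond the feasible ±k/W_c ≈ ±0.86 are clamped to the nearest achievable
sum; both the drawn target and the realized value are recorded in the truth
table.  With the default conditions the clamp affects well under 1% of
draws and biases group means by ≲0.003, inside the stated recovery
tolerances.

Determinism: one `numpy` Generator seeded from the config drives
everything; the same config is guaranteed byte-identical output
(tested, and re-tested through the full pipeline).

What the generator does **not** emulate: real Japanese prose (texts are
space-separated vocabulary words), follower/cascade structure, topic
content, geotags, or tweets whose keyword appears only in non-NFKC forms.
Passing recovery tests therefore shows the *pipeline* is correct and
well-calibrated under the stated statistical regimes — not that the
dictionary method itself is a valid sentiment measure for real tweets
(known failure modes of lexicon scoring, e.g. sarcasm, are inherited by
construction).

## Recovery surface

`recovery_report` checks three things on a generated year: the fitted
weekly target-mean slope against 7 × sentiment_slope within 3 fitted
standard errors; the RT-vs-target mean gap against bot_sentiment_offset
within ±0.02; and the sign of the weekly Fukushima count-ratio trend
against the configured logistic slope.  These are the quantities the
downstream scientific claims rest on (direction and size of drift, the
bot/RT negativity gap, rising Fukushima salience).

## Numerical and degenerate-input choices

- Missing cells (empty buckets, n < 2 F tests, zero denominators in
  ratios) propagate as missing (NaN / absent rows), never as 0.
- Lexicon values outside [−1, 1] are clipped with a warning; duplicate
  lexicon words keep the first value; an empty lexicon is fatal.
- ANOVA with zero within-group variance reports F = ∞ (p = 0) when means
  differ and F = 0 (p = 1) when they coincide.
- `per_capita_rate` rounds half away from zero (the convention behind the
  printed integer rates); population ≤ 0 is an error, not a 0 rate.
- The week label space (`W00` …) sorts lexicographically, which the
  bucketed tables rely on.

## Problem sizes

The default synthetic year is ≈100k tweets; the test suite uses that size
for trend/offset recovery and the acceptance script runs the same size
once.  Smaller corpora (≈2–10k) are used where the property under test is
structural (determinism, partition recovery, conservation) and does not
sharpen with n.
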