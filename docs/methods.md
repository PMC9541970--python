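# Methods

## The detection model

`ipvdetect` is a deterministic, rule-based phenotyping pipeline. The unit of
classification is the ED encounter; the label is binary (IPV-related or
not), and an encounter is positive under a given approach as soon as one
piece of unsuppressed evidence exists. There is no scoring, ranking or
learned component.

**Structured evidence (`icd`).** An encounter is positive if any of its
diagnosis codes belongs to the IPV code set (7 unique ICD-9 codes, 9 ICD-10
codes). Codes are compared uppercased with dot separators stripped, so
`995.81` and `99581` are the same code — EHR exports vary in dot usage.
Codes tagged with a revision are checked only against that revision's set;
untagged codes are checked against both. We deliberately do **not** switch
revision by visit date: revision tags on the codes themselves are more
reliable than the visit date around the October 2015 transition. The two
perpetrator codes (`E967.0`, `E967.9`) are treated as standalone evidence
like every other code; no co-occurrence constraint is imposed.

**Text evidence (`situational`, `extended`).** Each note is pre-processed
(below) and scanned for contiguous occurrences of lexicon phrases over the
surviving tokens. The `situational` approach uses the 23-phrase tier; the
`extended` approach uses the order-preserving union of both tiers (71 unique
phrases — "violence against women" appears in both). A match is suppressed
if any of its tokens lies in a negation or history scope. Overlapping
matches are all reported as evidence. Because the extended lexicon is a
superset, situational positivity implies extended positivity (tier
monotonicity), and adding phrases to a lexicon can never turn a positive
encounter negative.

The chief-complaint field, when present in an input record, is treated as
one more note (`author_role="other"`) and searched with the same pipeline.

## Pre-processing

Fixed stage order:

```
strip_template_blocks -> tokenize -> normalize
    -> mark_negation -> mark_history -> strip_punctuation -> match
```

Punctuation is kept through scoping because punctuation marks terminate
scopes; it is stripped only after history detection. Stop-class removal runs
*before* scoping, so scopes are resolved over surviving tokens plus
punctuation.

**Template stripping.** Lines matching configured shell-style wildcard
patterns (case-insensitive) are dropped before tokenization. This removes
auto-populated IPV screening-question blocks, whether completed or blank —
otherwise a blank "domestic violence screen: ___" line would label every
encounter that carries the form.

**Tokenization.** Letter runs (optionally slash-joined, so `h/o` and `h/x`
stay single tokens), digit runs, and single punctuation characters.
Whitespace is discarded.

**Normalization.** All word tokens are lowercased and stemmed (below).
Marked as removed: number tokens; word tokens shorter than 2 characters;
and tokens whose normalized form is in the temporal, preposition or pronoun
stop sets. Two protection mechanisms override removal: function words
occurring inside lexicon phrases ("by", "of", "or", "to", "with", "for",
"against", "and" — without which "assault by husband" could never match),
and the scoping cue vocabulary (without which "history **of**" could never
fire). The stop sets themselves are editable configuration; the packaged
temporal list is a pragmatic ED-note list ("last", "night", "ago", "days",
…), not a published resource.

**Stemming.** A minimal fixpoint stemmer rather than a full Porter stemmer:
strip `ed`/`ing`/`s` when a stem of ≥ 3 characters remains (with `ss`/`us`/
`is` guards on the plural rule), then a final `e` (length ≥ 4, not `ee`),
iterated until stable. The same function is applied to lexicon phrases,
scoping cues and note tokens, so matching happens in one normalized space:
"assaulted" → `assault`; "strangled" and "strangle" both → `strangl`;
"striking" and "strike" both → `strik`. Fixpoint iteration makes
normalization idempotent (property-tested). The cost is aggressive stems for
display purposes (`violenc`, `spous`); rendered debug output therefore shows
lowercased surfaces, not stems. Over-stemming collisions are possible in
principle but none occur among the 71 phrases, the cue sets and the stop
sets (asserted by the lexicon-distinctness and worked-example tests).

## Scoping

A simplified NegEx: only forward scopes, no pseudo-negation phrases, no
backward cues. When a negation cue (8 words: *denies, denied, deny, no,
non, not, without, unable*) is found, every surviving word token strictly
after it and before the next termination token (or sequence end) is flagged
`negated`. History cues (9 phrases: *history of, hx of, h/x of, ho of,
h/o of, hx, h/x, h/o, ho*) are matched longest-first — so "h/o of" is never
shadowed by "h/o" — and flag `in_history` over the same kind of scope,
reusing the negation termination set (the design keeps one scoping
mechanism; the canonical history example's "but" then correctly ends the
scope). The two flags are independent: a negation cue inside a history
scope still negates. Scopes from multiple cues union, and a token that is
itself a termination token is never flagged.

**The "and" decision.** The published termination-token table includes
"and", yet the published worked example negates *through* "and" ("…
use_neg and_neg intimate_neg …"). The default configuration drops "and"
from the terminators so the operational example reproduces; a
`faithful_table3=True` switch restores the table verbatim. Ambiguous
standalone cues (notably "ho", which collides with other clinical
abbreviations) stay in the default set for fidelity to the published list
but can be disabled individually via `ScopingConfig.without_cues`.

Scoping correctness is verified against a brute-force oracle that, for
every (cue, token) pair, checks "no terminator strictly between" — 10,000
random sequences of ≤ 30 tokens in the acceptance suite, plus
hypothesis-driven cases.

## Known false-positive sources (kept for fidelity)

Whole-token matching means `ipv` also fires on the inactivated polio
vaccine abbreviation, and "domestic dispute" fires on non-partner family
conflict. These are retained as the default behavior; an optional
`term_exclusions` parameter (e.g. `("ipv vaccine",)`) vetoes any term match
falling inside an exclusion-context occurrence, and is **off** by default.

## Synthetic corpus generator

The generator emulates the note phenomena the detector must handle, not
clinical narrative realism. Each truth-positive encounter embeds one
uniformly chosen phrase from the 71-phrase union, realized in one of four
styles (verbatim; temporal/possessive filler — "assault **last night** by
**her** husband"; inflected head verb — "assaulted", "strangling"; both)
inside a cue-free wrapper sentence. Only regular inflections that the
stemmer provably undoes are used, and every wrapper is cue-free, so
positives are machine-recoverable *by construction*. Negative encounters
independently receive negated mentions, history mentions, screening-template
blocks and distractor sentences at configured rates, on top of benign
filler drawn from a vocabulary disjoint from the lexicons (so no phrase can
form across stripped punctuation).

Defaults (the package's study conditions): `n_encounters=1000`,
`prevalence=0.1` (a desk-scale rate that puts 100 positives in a
1,000-encounter corpus; true ED prevalence is an order of magnitude lower),
`negated_mention_rate=0.2`, `history_mention_rate=0.1`,
`template_block_rate=0.1`, `distractor_rate=0.1`, and
`icd_coding_rate=0.013` — the probability that a true IPV encounter also
carries an IPV ICD code, reflecting the severe under-coding observed in
practice (on the order of 1% of term-identified encounters). Positive
allocation is exact (`round(prevalence·n)`, positions shuffled by the seed)
so tests can assert counts without tolerance; ICD coding is Bernoulli per
positive. Generation is deterministic given the seed (byte-identical JSONL).

**What passing closed-loop tests show — and don't.** With distractors and
templates off, precision = recall = 1.0 against generator truth for every
seed demonstrates internal consistency: normalization undoes exactly the
surface variation the realizer introduces, and scoping suppresses exactly
the wrapped mentions. It does **not** estimate performance on real notes,
where phrasing outside the lexicon, misspellings, unusual negation syntax
and history descriptions outside the cue list all cause misses the
generator cannot produce.

## Evaluation harness

`confusion` supports two truth modes. *Review* mode mirrors manual chart
review of flagged cases: truth exists only for predicted positives,
precision is computed and recall is reported as undefined (`None`).
*Full* mode (possible with synthetic truth) computes both. Feeding the
published review tallies through the review-mode scorer reproduces the
printed figures: 16 confirmed of 199 ICD-flagged charts → 8.04% ≈ 8%;
1,790 of 1,798 term-flagged charts → 99.56% (printed as 99.5%; the exact
value is reported and rounding left to the caller).

`sample_for_review` draws `round(fraction·n_positive)` positives uniformly
(seeded), optionally stratified by visit year with largest-remainder
allocation (each year's share preserved within ±1). `compare_approaches`
reports Venn counts of two approaches' positive sets, optionally at the
distinct-patient level via an encounter→patient mapping.

## Degenerate inputs and numeric edges

Empty note text tokenizes to an empty sequence and classifies negative;
encounters with no notes and no codes are negative under every approach.
Duplicate encounter ids are a hard error (silent double counting would
corrupt patient-level summaries). Unparseable diagnosis codes are skipped
with a warning rather than failing a whole corpus. Precision/recall are
`None` (never NaN) when their denominators are zero. A cue as the final
token yields an empty scope.

## Problem sizes

The test suite runs closed-loop recovery at n = 1,000 over five seeds,
oracle equivalence on 10,000 random sequences, and recoverability of all
71 phrases × 4 realization styles; the acceptance script uses n = 1,000
(closed loop) and n = 500 (suppression). These sizes make every stochastic
property stable across seeds while keeping a full run under a minute.

## Limitations

* Detection is bounded by the lexicon: phrasing outside the 71 terms is
  invisible, and no spelling correction is attempted.
* History and negation cues are closed lists; circumlocutions ("this
  happened years back") escape suppression.
* The `ipv`/vaccine and "domestic dispute" collisions inflate false
  positives unless exclusion contexts are enabled.
* Review-mode evaluation cannot measure recall; only full-truth (synthetic)
  corpora can.
* The generator's template bank is invented; its rates are desk-scale
  settings, not epidemiological estimates.
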