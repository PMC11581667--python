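# Methods

This note documents the models and procedures implemented in `plainlens`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic fixtures can show.

## Text model

A document is parsed as paragraphs → sentences → tokens. Paragraphs split
on blank lines. Sentences split on `. ! ?` followed by whitespace, with an
abbreviation whitelist (`Dr., Mr., Mrs., Ms., Prof., St., e.g., i.e., etc.,
vs., cf., fig., al., approx.` and any single letter) blocking false splits;
markdown headings and bullet lines, and any trailing fragment without a
terminator, each count as one sentence. Tokens are words (including
hyphenated compounds and internal apostrophes), numerals, or punctuation.
Declared conventions, chosen for reproducible counts on markdown-ish health
copy:

- numerals are not words and contribute zero syllables, so "2023" is never
  polysyllabic (readability formulas are calibrated on prose words);
- hyphenated compounds are one token whose syllables sum over the parts;
- case-folding happens only in the `normalized` field — acronym detection
  needs the surface case.

Parsing is deterministic: no global state, no randomness, identical input
gives an identical document, and counts are additive over blank-line
concatenation (property-tested).

### Syllable counting

Dictionary first, heuristic second: a bundled exception table
(`data/syllables.tsv`, ~35 entries for words the heuristic misjudges, e.g.
*idea*, *science*, *iatrogenic*), then a vowel-group count with three
adjustments — terminal silent *e* (unless *-le*), silent *-ed* after a
consonant other than *t/d*, and silent *-es* after most consonants. The
result is always ≥ 1. English syllabification has no clean closed form;
this trades rare errors on unusual words for full determinism and zero
runtime dependencies. Words feeding exact-count tests are verified against
the counter explicitly.

### Part-of-speech tagging

A coarse rule tagger (tags: DET, PRON, PREP, CONJ, AUX, NEG, NOUN, VERB,
ADJ, ADV, NUM, PUNCT): enumerated closed-class function words, then a
bundled open-class tag lexicon (~180 common words), then suffix rules
(-ly → ADV, -ing/-ed → VERB, noun and adjective suffixes), defaulting to
NOUN. This is deliberately *not* a statistical tagger: its two consumers —
the passive-voice pattern and the content-word ratio — need stable,
explainable decisions more than broad-coverage accuracy. Known
simplifications: lexical *have/do* are conflated with their auxiliary
readings (slightly deflating lexical density), and *not/never* are tagged
NEG (excluded from content words).

## The six assessments

**SMOG.** `3.1291 + 1.0430·√(30P/S)`, the precise formula, with constants
exposed in `assessments.py`. The 30-sentence normalization `P·30/S` makes
the score defined for any S ≥ 1 — necessary because the texts this tool
targets run ~200 words, far short of SMOG's 30-sentence sampling protocol.
The score is strictly increasing in P at fixed S and invariant under text
duplication (both tested).

**Complex language.** Flag = uncommon ∪ acronym ∪ thesaurus-hit, counted
once per token; score = 100 · flagged / words. "Uncommon" means a
Zipf-scale frequency score strictly below `uncommon_threshold` (default
3.0, roughly "rarer than ~1 per million words"), or absence from the
frequency lexicon — absence is treated as uncommon by design, which is the
conservative reading when the lexicon is trusted to contain common English.
The bundled ~500-word frequency list is a hand-curated synthetic fixture
with Zipf-law scores by rank; it stands in for the large proprietary
corpora such tools use in production and is *not* a claim about English
word frequencies. The acronym rule is purely orthographic (≥2 capitals, no
lowercase, whitelist override): no published rule exists to copy, so the
simplest testable contract was chosen.

**Passive voice.** A form of *to be* followed, within the sentence, by a
past participle, with at most two intervening adverb/negation tokens;
punctuation or any other part of speech blocks the pattern. Participles are
recognised from an irregular-participle list plus the *-ed* suffix (with a
non-participle exception list: *indeed*, *hundred*, …). "Get"-passives and
bare participials are deliberately not counted — the implemented pattern is
exactly the be+participle definition, no more. Predicative adjectives in
*-ed* ("was tired") do count; that is inherent to a pattern-based detector
without a dependency parse.

**Lexical density** = 100 · content words / words, content = NOUN, lexical
VERB, ADJ, ADV. **Lexical diversity** = moving-average type-token ratio
with window 50 (MATTR-50), falling back to plain TTR below 50 words —
MATTR is length-invariant, which plain TTR is not. **Text structure** is a
minimal declared metric set: mean words/sentence, mean sentences/paragraph,
% sentences over 25 words (the long-sentence threshold common in
plain-language guidance). **Person-centered language** scans word n-grams
(longest match first, case-insensitive) against a phrase → preferred-phrase
wordlist.

Report values are rounded half-up to 2 decimals at serialization only;
internal values are unrounded.

## Trial analysis

The design analyzed is a parallel two-arm trial where every participant
revises the same three texts and the per-participant outcome is the mean
over the three texts.

- **ITT**: every randomized participant. Carry-forward imputation is
  text-wise: any unsubmitted text receives the *original* text's scores
  (assume no changes were made). Participants who submitted only 1–2 texts
  are noncompleters for set membership, but their submitted texts keep
  their scores — the declared rule where a single "completer" bit would be
  ambiguous. The default baseline applies the published original-text
  scores (195 words, grade 13.97, 25.87% complexity, 5 passives, expert
  ratings 5.0/2.7/5.0) uniformly to the three texts; callers can supply
  per-text baselines.
- **PP**: completers only; intervention completers must have attended
  training; control participants who used the intervention tool are
  excluded.
- **Effects**: mean difference with pooled-variance *t* CI and p-value —
  algebraically the simple-linear-regression contrast on an arm indicator
  (verified against OLS in the tests); Welch available behind a flag.
  Cohen *d* is the classical MD / pooled SD. Contrasts are oriented so
  positive = improvement: control − intervention for objective scores
  (lower is better), intervention − control for expert ratings (higher is
  better).
- **Mann-Whitney U** (default for the median-reported, ceiling-skewed
  expert ratings *content* and *meaning retention*): midrank ties; the
  two-sided exact p is the permutation probability of a rank sum at least
  as far from its null mean as observed, computed by a count dynamic
  program over doubled midranks — mathematically identical to enumerating
  all C(n_a+n_b, n_a) group assignments, including under ties, and
  verified against literal brute-force enumeration for all size pairs with
  n_a+n_b ≤ 10. The exact route is used while n_a·n_b ≤ 400 (the DP makes
  this cheap; counts stay below 2⁵³ so float64 arithmetic is exact);
  beyond that, the tie-corrected normal approximation with continuity
  correction (agrees with standard implementations to ~10 decimal places).
- **SUS**: standard 0–100 scoring (odd items response−1, even items
  5−response, total × 2.5); **TAM**: subscale means on 1–5.
- No multiplicity adjustment: secondary contrasts are exploratory by
  design.

## Synthetic generators

**Texts.** Sentences are assembled from templated frames over annotated
word pools — active `The <slot> <verb> the <slot> …` and passive
`The <slot> was <participle> by the <slot> …` — where every pool word
carries its syllable count and complex-flag status, pool words never
include be-forms or participles, and the participle appears only
immediately after the frame's *was*. Consequently S, word count, P,
flagged-word count and passive instances are known exactly by
construction, giving an oracle that is independent of the parser. The
pool annotations themselves are asserted against the syllable counter and
lexicon queries in the tests, keeping the two routes honest. Default spec:
13 sentences × 15 words = 195 words, polysyllable rate 0.24, complex rate
0.18, passive rate 0.38 — chosen once to emulate ~200-word health texts at
about a grade-14 reading level with ~5 passives, the profile of the trial
stimuli. What this oracle does **not** show: performance on natural prose
(real clause structure, rare words outside the pools, inconsistent
formatting); the generator texts are grammatically monotone by design.

**Trials.** Per-arm participant-level outcomes are drawn from normal
distributions (defaults: the published ITT group means/SDs) clipped to
declared plausibility bounds (grades [0, 20], percentages [0, 100],
passives [0, 10], ratings [1, 5]); a zero-sum per-text jitter (SD 0.15 ×
arm SD) spreads each participant's value over the three texts so the
participant mean is exactly the drawn value and the arm-level moments are
preserved. Dropout defaults 23/86 and 11/95 per arm and one contaminated
control completer mirror the published participant flow. One bookkeeping
ambiguity is resolved by declaration: the contaminated participant is
drawn from the control completers, so the default PP control set is one
smaller than the completer count. The parameter-recovery simulation runs
500 replicates at the ITT generating parameters with dropout 0 — the
published group summaries already describe the ITT outcome distribution,
so simulating additional dropout plus carry-forward would double-count
attrition. Empirical CI coverage lands near 0.93–0.94 rather than 0.95:
the pooled-t is mildly liberal here because the larger arm has the smaller
variance, which is a property of the published design, not a defect of the
estimator code (Welch is available where that matters).

Sizes were chosen so the full test suite runs in well under a minute and
the acceptance script in a few seconds: 1,000 oracle texts of 2–11
sentences, 500 trial replicates, exact Mann-Whitney checks to n = 10.

## Known limitations

- The tagger and syllable counter are rule-based; on open-domain prose the
  assessments approximate, rather than reproduce, any specific deployed
  editor's scores — no exact-match claim is made against commercial tools.
- The bundled lexicons are fixtures; production scoring needs real
  frequency/thesaurus resources (TSV formats documented in
  `plainlens/lexicons.py`).
- The printed effect-size values of the evaluation this package mirrors
  (e.g. a Cohen *d* of 0.99 for the grade-reading outcome) are not
  derivable from the printed group summaries under any standard pooling;
  the classical formula gives ≈1.14 from those summaries. The package
  computes the classical quantity and does not attempt to match the
  printed ones.
- Expert (PEMAT-style) ratings are human inputs; the package aggregates
  them but does not automate the instrument.
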