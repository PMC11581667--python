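# plainlens

Objective plain-language assessment of written health information, with a
two-arm trial analysis pipeline and synthetic fixtures.

Health information is routinely written well above the grade-8 reading level
that health-literacy guidelines recommend, which disadvantages the people who
most need to understand it. `plainlens` implements the family of objective
assessments used by plain-language editing tools for health writing —
readability, complex language, passive voice, lexical density and diversity,
text structure, and person-centered language — as a deterministic, scriptable
library and CLI. It also implements the outcome-analysis pipeline of the kind
of randomized trial used to evaluate such tools: intention-to-treat and
per-protocol analysis-set construction, two-group effect estimation, exact
Mann-Whitney tests, and usability scoring.

## The assessments

For a parsed document with `S` sentences and `P` polysyllabic words
(3+ syllables):

- **SMOG grade** (readability, the primary outcome measure):
  `grade = 3.1291 + 1.0430 · √(30 · P / S)` — McLaughlin's precise closed
  form with 30-sentence normalization, so texts of any length are scorable.
- **Complex language**: the percentage of words that are uncommon in English
  (Zipf-style frequency score below a threshold, or absent from the
  frequency lexicon), acronyms (≥2 capitals, no lowercase, not whitelisted),
  or have a simpler thesaurus alternative. A word meeting several criteria
  counts once.
- **Passive voice**: instances of a form of *to be* followed by a past
  participle, allowing up to two intervening adverbs/negations
  ("was **not** fully *reviewed*").
- **Lexical density**: percentage of content words (nouns, lexical verbs,
  adjectives, adverbs).
- **Lexical diversity**: moving-average type-token ratio (window 50).
- **Text structure**: mean words/sentence, mean sentences/paragraph, and the
  share of sentences longer than 25 words.
- **Person-centered language**: longest-match flags with preferred
  person-first alternatives ("diabetic" → "person with diabetes").

The trial module estimates two-arm effects from participant-level data or
printed group summaries: mean differences with pooled-variance *t* confidence
intervals (numerically identical to simple linear regression on an arm
indicator), classical Cohen *d* (MD / pooled SD), exact Mann-Whitney *U*
for skewed outcomes, SUS/TAM acceptability scoring, and the carry-forward
imputation rule for intention-to-treat analysis (noncompleters keep the
original texts' scores).

## Worked example

```python
from plainlens import assess

text = (
    "Your medication should be taken with food every morning. "
    "Treatment was commenced by your physician to reduce hypertension. "
    "Diabetic patients should utilize the clinic hotline if pain continues."
)
print(assess(text).to_json(indent=2))
```

prints (abridged):

```json
{
  "smog_grade": 11.21,
  "complex_pct": 42.86,
  "passive_count": 2,
  "lexical_density_pct": 57.14,
  "lexical_diversity": 0.93,
  "person_centered_flags": [
    {"term": "Diabetic", "suggestion": "person with diabetes", "position": 18}
  ],
  "word_count": 28
}
```

Read: this passage needs about 11 years of schooling (target is 8–10); 42.9%
of its words are complex ("medication", "commenced", "physician",
"hypertension", "utilize" all have simpler alternatives); two sentences are
passive ("be taken", "was commenced"); and "Diabetic patients" should be
rewritten person-first. Rewriting it as "Take your medicine with food every
morning…" drops the grade and zeroes the flags.

The same scores are available in batch from the shell:

```bash
plainlens score docs_folder/ --out-csv report.csv --out-json report.json
plainlens analyze trial.csv --out-dir results/      # ITT + PP outcome table
plainlens fixtures make-text --seed 5 --out sample.txt --truth truth.json
plainlens fixtures make-trial --seed 5 --out trial.csv
```

`fixtures make-text` writes a synthetic health-style text assembled from
annotated word pools so that its sentence, polysyllable, complex-word and
passive counts are known exactly by construction — the package's oracle.
`fixtures make-trial` simulates a two-arm trial (default: arm sizes 86/95,
per-arm dropout 23/86 and 11/95, one contaminated control participant, and
outcome distributions matching a published evaluation of such a tool).

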