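"""The six objective plain-language assessments and the combined report.

The assessments mirror a real-time plain-language editor for health texts:

1.  **Readability** — SMOG grade, McLaughlin's precise closed form
    ``3.1291 + 1.0430 * sqrt(P * 30 / S)`` where ``P`` is the number of
    polysyllabic words (3+ syllables) and ``S`` the number of sentences.
    The ``30/S`` factor normalizes to SMOG's 30-sentence calibration so
    texts of any length are scorable.
2.  **Complex language** — percentage of words that are uncommon in
    English, acronyms, or have a simpler thesaurus alternative.  A word
    satisfying several criteria is counted once (union, not sum).
3.  **Passive voice** — instances of a form of *to be* followed by a past
    participle, allowing at most two intervening adverbs/negations.
4.  **Lexical density** — percentage of content words (nouns, lexical
    verbs, adjectives, adverbs).
5.  **Lexical diversity** — moving-average type-token ratio, window 50
    (plain TTR below 50 words).
6.  **Text structure** — mean words/sentence, mean sentences/paragraph,
    and the share of sentences longer than 25 words.

Plus **person-centered language** flags with suggested alternatives.
All scores are pure functions of (text, lexicon bundle, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from ._postag import BE_FORMS, CONTENT_TAGS, is_past_participle
from ._util import round_half_up
from .errors import DomainError, EmptyDocumentError
from .lexicons import (
    LexiconBundle,
    default_bundle,
    detect_acronym,
    is_uncommon,
    thesaurus_alternatives,
)
from .textcore import Document, segment

__all__ = [
    "SMOG_INTERCEPT",
    "SMOG_SLOPE",
    "AssessmentReport",
    "smog_grade",
    "complex_language_pct",
    "passive_voice_count",
    "lexical_density_pct",
    "lexical_diversity",
    "person_centered_flags",
    "text_structure",
    "assess",
]

SMOG_INTERCEPT = 3.1291
SMOG_SLOPE = 1.0430
MATTR_WINDOW = 50
LONG_SENTENCE_WORDS = 25
REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PersonCenteredFlag:
    term: str
    suggestion: str
    position: int  # index into the document's word-token sequence


@dataclass
class AssessmentReport:
    """The six objective scores for one document (unrounded internally)."""

    smog_grade: float
    complex_pct: float
    passive_count: int
    lexical_density_pct: float
    lexical_diversity: float
    structure: dict[str, float]
    person_centered_flags: list[PersonCenteredFlag] = field(default_factory=list)
    word_count: int = 0

    def to_dict(self, rounded: bool = True) -> dict:
        r2 = (lambda x: round_half_up(x, 2)) if rounded else (lambda x: x)
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "smog_grade": r2(self.smog_grade),
            "complex_pct": r2(self.complex_pct),
            "passive_count": self.passive_count,
            "lexical_density_pct": r2(self.lexical_density_pct),
            "lexical_diversity": r2(self.lexical_diversity),
            "structure": {k: r2(v) for k, v in self.structure.items()},
            "person_centered_flags": [
                {"term": f.term, "suggestion": f.suggestion, "position": f.position}
                for f in self.person_centered_flags
            ],
            "word_count": self.word_count,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _require_words(doc: Document) -> None:
    if doc.word_count < 1:
        raise EmptyDocumentError("document contains no words")


def smog_grade(doc: Document) -> float:
    """SMOG grade: 3.1291 + 1.0430 * sqrt(P * 30 / S)."""
    if doc.sentence_count < 1:
        raise DomainError("SMOG needs at least one sentence")
    p, s = doc.polysyllable_count, doc.sentence_count
    return SMOG_INTERCEPT + SMOG_SLOPE * math.sqrt(p * 30.0 / s)


def complex_language_pct(doc: Document, bundle: LexiconBundle | None = None) -> float:
    """Percentage of words flagged as uncommon, acronyms, or thesaurus hits.

    Each word token counts at most once even when it satisfies several
    criteria.
    """
    _require_words(doc)
    bundle = bundle if bundle is not None else default_bundle()
    flagged = 0
    for tok in doc.word_tokens:
        if (
            is_uncommon(tok.normalized, bundle)
            or detect_acronym(tok, bundle)
            or thesaurus_alternatives(tok.normalized, bundle)
        ):
            flagged += 1
    return 100.0 * flagged / doc.word_count


def passive_voice_count(doc: Document) -> int:
    """Instances of be-form + past participle, <= 2 intervening adverbs/negations."""
    count = 0
    for sentence in doc.sentences:
        toks = sentence.tokens
        i = 0
        while i < len(toks):
            tok = toks[i]
            if tok.is_word and tok.normalized in BE_FORMS:
                j = i + 1
                skipped = 0
                while j < len(toks):
                    nxt = toks[j]
                    if not nxt.is_word:
                        break  # punctuation blocks the pattern
                    if is_past_participle(nxt.normalized) and nxt.pos_tag not in (
                        "AUX",
                    ):
                        count += 1
                        i = j
                        break
                    if nxt.pos_tag in ("ADV", "NEG") and skipped < 2:
                        skipped += 1
                        j += 1
                        continue
                    break
            i += 1
    return count


def lexical_density_pct(doc: Document) -> float:
    """Share of content words (NOUN, lexical VERB, ADJ, ADV) among all words."""
    _require_words(doc)
    content = sum(1 for t in doc.word_tokens if t.pos_tag in CONTENT_TAGS)
    return 100.0 * content / doc.word_count


def lexical_diversity(doc: Document, window: int = MATTR_WINDOW) -> float:
    """Moving-average type-token ratio (window 50); plain TTR for short texts."""
    _require_words(doc)
    types = [t.normalized for t in doc.word_tokens]
    n = len(types)
    if n < window:
        return len(set(types)) / n
    ratios = [
        len(set(types[i : i + window])) / window for i in range(n - window + 1)
    ]
    return sum(ratios) / len(ratios)


def person_centered_flags(
    doc: Document, bundle: LexiconBundle | None = None
) -> list[PersonCenteredFlag]:
    """Case-insensitive longest-match scan for person-centered wordlist terms."""
    bundle = bundle if bundle is not None else default_bundle()
    if not bundle.person_centered:
        return []
    max_len = max(len(k.split()) for k in bundle.person_centered)
    words = doc.word_tokens
    flags: list[PersonCenteredFlag] = []
    i = 0
    while i < len(words):
        for n in range(min(max_len, len(words) - i), 0, -1):
            phrase = " ".join(w.normalized for w in words[i : i + n])
            if phrase in bundle.person_centered:
                surface = " ".join(w.surface for w in words[i : i + n])
                flags.append(
                    PersonCenteredFlag(
                        term=surface,
                        suggestion=bundle.person_centered[phrase],
                        position=i,
                    )
                )
                i += n
                break
        else:
            i += 1
    return flags


def text_structure(doc: Document) -> dict[str, float]:
    """Mean words/sentence, mean sentences/paragraph, % sentences > 25 words."""
    if doc.sentence_count < 1:
        raise EmptyDocumentError("document contains no sentences")
    sent_lengths = [len(s.word_tokens) for s in doc.sentences]
    long_share = 100.0 * sum(1 for n in sent_lengths if n > LONG_SENTENCE_WORDS) / len(
        sent_lengths
    )
    return {
        "mean_words_per_sentence": doc.word_count / doc.sentence_count,
        "mean_sentences_per_paragraph": doc.sentence_count / doc.paragraph_count,
        "pct_sentences_over_25_words": long_share,
    }


def assess(text: str, bundle: LexiconBundle | None = None) -> AssessmentReport:
    """Run segmentation plus all six assessments on one text."""
    doc = segment(text)
    _require_words(doc)
    bundle = bundle if bundle is not None else default_bundle()
    return AssessmentReport(
        smog_grade=smog_grade(doc),
        complex_pct=complex_language_pct(doc, bundle),
        passive_count=passive_voice_count(doc),
        lexical_density_pct=lexical_density_pct(doc),
        lexical_diversity=lexical_diversity(doc),
        structure=text_structure(doc),
        person_centered_flags=person_centered_flags(doc, bundle),
        word_count=doc.word_count,
    )
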