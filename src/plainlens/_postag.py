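"""Coarse rule-based part-of-speech tagging.

A lightweight tagger sufficient for the two consumers in this package:
passive-voice pattern matching (be-form + past participle) and lexical
density (content-word ratio).  Closed-class function words are enumerated
in code, open-class words fall back to a bundled tag lexicon and then to
suffix rules.  The tag set is coarse by design:

    DET PRON PREP CONJ AUX NEG NOUN VERB ADJ ADV NUM PUNCT

Auxiliaries (all forms of *be*, *have*, *do*, and the modals) are tagged
AUX and are never content words; lexical uses of *have* are conflated
with the auxiliary, a declared simplification.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

BE_FORMS = frozenset({"am", "is", "are", "was", "were", "be", "been", "being"})

_AUX = BE_FORMS | {
    "have", "has", "had", "having", "do", "does", "did",
    "can", "could", "will", "would", "shall", "should", "may", "might", "must",
}

_DET = frozenset({
    "the", "a", "an", "this", "that", "these", "those", "each", "every",
    "some", "any", "no", "both", "either", "neither", "all", "most",
    "several", "few", "many", "much", "its", "his", "her", "their", "our",
    "my", "your",
})

_PRON = frozenset({
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "us", "them",
    "who", "whom", "whose", "which", "what", "someone", "anyone", "everyone",
    "something", "anything", "everything", "nothing", "one", "themselves",
    "himself", "herself", "itself", "myself", "yourself", "ourselves",
})

_PREP = frozenset({
    "of", "in", "on", "at", "to", "for", "with", "by", "from", "about",
    "into", "onto", "over", "under", "after", "before", "between", "through",
    "during", "without", "within", "against", "among", "around", "across",
    "behind", "beyond", "near", "off", "out", "up", "down", "than", "as",
    "per", "via", "until", "upon",
})

_CONJ = frozenset({
    "and", "or", "but", "nor", "so", "yet", "if", "because", "although",
    "though", "while", "when", "where", "whether", "since", "unless",
    "that", "once",
})

_NEG = frozenset({"not", "n't", "never"})

#: Irregular past participles recognised by the passive-voice pattern.
IRREGULAR_PARTICIPLES = frozenset({
    "given", "taken", "made", "done", "seen", "known", "shown", "written",
    "found", "told", "kept", "held", "sent", "built", "spent", "left",
    "lost", "put", "set", "read", "said", "paid", "sold", "bought",
    "brought", "thought", "taught", "caught", "chosen", "spoken", "broken",
    "eaten", "driven", "drawn", "grown", "thrown", "worn", "born", "begun",
    "run", "won", "met", "felt", "meant", "led", "fed", "heard",
    "understood", "hidden", "forgotten", "frozen", "given", "gotten",
    "hurt", "cut", "hit", "spread", "prescribed", "meant",
})

#: Words ending in "ed" that are not past participles.
_ED_NON_PARTICIPLES = frozenset({
    "need", "indeed", "naked", "wicked", "sacred", "hatred", "hundred",
    "kindred", "bed", "red", "speed", "feed", "seed", "breed", "bleed",
    "exceed", "proceed", "succeed", "shed", "wed",
})

_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ism", "ance", "ence",
                  "ship", "hood", "ology", "itis")
_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ical", "ish", "less",
                 "ary", "ic", "al")


@lru_cache(maxsize=1)
def _tag_lexicon() -> dict[str, str]:
    text = resources.files("plainlens.data").joinpath("postags.tsv").read_text("utf-8")
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, _, tag = line.partition("\t")
        table[word.casefold()] = tag.strip()
    return table


def is_past_participle(normalized: str) -> bool:
    """Heuristic past-participle test used by the passive-voice pattern."""
    if normalized in IRREGULAR_PARTICIPLES:
        return True
    return (
        len(normalized) >= 4
        and normalized.endswith("ed")
        and normalized not in _ED_NON_PARTICIPLES
    )


def tag_word(normalized: str) -> str:
    if normalized in _AUX:
        return "AUX"
    if normalized in _NEG:
        return "NEG"
    if normalized in _DET:
        return "DET"
    if normalized in _PRON:
        return "PRON"
    if normalized in _PREP:
        return "PREP"
    if normalized in _CONJ:
        return "CONJ"
    lex = _tag_lexicon()
    if normalized in lex:
        return lex[normalized]
    if normalized.endswith("ly") and len(normalized) > 3:
        return "ADV"
    if normalized.endswith("ing") and len(normalized) > 4:
        return "VERB"
    if is_past_participle(normalized):
        return "VERB"
    for suf in _NOUN_SUFFIXES:
        if normalized.endswith(suf) and len(normalized) > len(suf) + 1:
            return "NOUN"
    for suf in _ADJ_SUFFIXES:
        if normalized.endswith(suf) and len(normalized) > len(suf) + 2:
            return "ADJ"
    return "NOUN"


CONTENT_TAGS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})


def tag_tokens(tokens: list) -> list:
    """Assign a coarse tag to every word token; non-words keep theirs."""
    from dataclasses import replace

    return [
        replace(t, pos_tag=tag_word(t.normalized)) if t.is_word else t
        for t in tokens
    ]
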