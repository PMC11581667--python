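"""Deterministic text segmentation, tokenization, and syllable counting.

Every assessment consumes the :class:`Document` produced here, so the rules
are deliberately simple and fully declared:

* paragraphs split on blank lines;
* sentences split on ``. ! ?`` with an abbreviation whitelist; markdown
  headings and bullet fragments without terminal punctuation each count as
  one sentence;
* hyphenated compounds are a single token whose syllables sum over parts;
* numerals are not words and contribute zero syllables;
* a word is polysyllabic when it has three or more syllables.

Parsing the same text twice yields an identical document: there is no
global state and no randomness anywhere in this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import DomainError, EmptyDocumentError

__all__ = ["Token", "Sentence", "Document", "segment", "tokenize", "count_syllables"]

#: Abbreviations that never terminate a sentence (lookup is case-folded,
#: trailing periods stripped).
ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
    "e.g", "i.e", "etc", "vs", "cf", "fig", "al", "approx",
}

_TOKEN_RE = re.compile(
    r"(?P<word>[A-Za-z]+(?:['’][A-Za-z]+)*(?:-[A-Za-z]+(?:['’][A-Za-z]+)*)*)"
    r"|(?P<num>\d+(?:[.,]\d+)*)"
    r"|(?P<punct>\S)"
)

_TERMINATOR_RE = re.compile(r"[.!?]+(?=\s|$)")
_HEADING_RE = re.compile(r"^\s{0,3}(#{1,6}\s+|[-*+]\s+|\d+[.)]\s+)")


@dataclass(frozen=True)
class Token:
    """One token with its normalized form, syllable count, and coarse POS tag."""

    surface: str
    normalized: str
    syllables: int
    is_word: bool
    pos_tag: str

    @property
    def is_polysyllabic(self) -> bool:
        return self.is_word and self.syllables >= 3


@dataclass(frozen=True)
class Sentence:
    text: str
    tokens: tuple[Token, ...]

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)


@dataclass(frozen=True)
class Document:
    """Parsed text: paragraphs of sentences, with the SMOG inputs S and P."""

    raw_text: str
    paragraphs: tuple[tuple[Sentence, ...], ...]
    word_count: int
    sentence_count: int
    polysyllable_count: int

    @property
    def sentences(self) -> tuple[Sentence, ...]:
        return tuple(s for p in self.paragraphs for s in p)

    @property
    def tokens(self) -> tuple[Token, ...]:
        return tuple(t for s in self.sentences for t in s.tokens)

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)

    paragraph_count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "paragraph_count", len(self.paragraphs))


# ---------------------------------------------------------------------------
# syllable counting

@lru_cache(maxsize=1)
def _syllable_exceptions() -> dict[str, int]:
    text = resources.files("plainlens.data").joinpath("syllables.tsv").read_text("utf-8")
    table: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, _, n = line.partition("\t")
        table[word.casefold()] = int(n)
    return table


_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def _heuristic_syllables(w: str) -> int:
    """Vowel-group count with silent-e, -ed and -es adjustments; >= 1."""
    n = len(_VOWEL_GROUP_RE.findall(w))
    if n > 1 and w.endswith("e") and not w.endswith("le"):
        n -= 1
    elif n > 1 and w.endswith("ed") and len(w) > 3 and w[-3] not in "aeiouytd":
        n -= 1
    elif (
        n > 1
        and w.endswith("es")
        and len(w) > 3
        and w[-3] not in "aeiouysxz"
        and w[-4:-2] not in ("ch", "sh")
    ):
        n -= 1
    return max(n, 1)


def count_syllables(word: str) -> int:
    """Count syllables of one alphabetic token.

    Exception-dictionary lookup first, then the vowel-group heuristic.
    Hyphenated compounds sum over their parts.  Non-alphabetic input
    raises :class:`DomainError`.
    """
    if not word or not re.search(r"[A-Za-z]", word):
        raise DomainError(f"cannot count syllables of non-alphabetic input {word!r}")
    if "-" in word:
        return sum(count_syllables(p) for p in word.split("-") if p)
    w = word.casefold().replace("'", "").replace("’", "")
    w = re.sub(r"[^a-z]", "", w)
    exc = _syllable_exceptions()
    if w in exc:
        return exc[w]
    return _heuristic_syllables(w)


# ---------------------------------------------------------------------------
# tokenization

def tokenize(sentence_text: str) -> list[Token]:
    """Tokenize one sentence into word, numeral, and punctuation tokens.

    Words get a syllable count and a coarse POS tag; numerals and
    punctuation are not words and carry zero syllables.
    """
    from . import _postag  # deferred: _postag imports nothing from here

    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(sentence_text):
        surface = m.group()
        if m.lastgroup == "word":
            tokens.append(
                Token(
                    surface=surface,
                    normalized=surface.casefold(),
                    syllables=count_syllables(surface),
                    is_word=True,
                    pos_tag="",
                )
            )
        elif m.lastgroup == "num":
            tokens.append(Token(surface, surface, 0, False, "NUM"))
        else:
            tokens.append(Token(surface, surface, 0, False, "PUNCT"))
    return _postag.tag_tokens(tokens)


# ---------------------------------------------------------------------------
# segmentation

def _split_sentences(block: str) -> list[str]:
    sentences: list[str] = []
    start = 0
    for m in _TERMINATOR_RE.finditer(block):
        if m.group().startswith("."):
            prefix = block[start : m.start()]
            wm = re.search(r"([A-Za-z][\w.]*)\s*$", prefix)
            if wm is not None and m.end() < len(block):
                w = wm.group(1).casefold().rstrip(".")
                if w in ABBREVIATIONS or len(w) == 1:
                    continue
        sent = block[start : m.end()].strip()
        if sent:
            sentences.append(sent)
        start = m.end()
    rest = block[start:].strip()
    if rest:
        sentences.append(rest)
    return sentences


def _paragraph_sentences(paragraph: str) -> list[str]:
    """Split one paragraph into sentence strings, honouring markdown lines."""
    units: list[str] = []
    plain: list[str] = []
    for line in paragraph.splitlines():
        if _HEADING_RE.match(line):
            if plain:
                units.extend(_split_sentences(" ".join(plain)))
                plain = []
            stripped = _HEADING_RE.sub("", line).strip()
            if stripped:
                units.extend(_split_sentences(stripped))
        elif line.strip():
            plain.append(line.strip())
    if plain:
        units.extend(_split_sentences(" ".join(plain)))
    return units


def segment(text: str) -> Document:
    """Parse text into a :class:`Document`.

    Raises :class:`EmptyDocumentError` for empty or whitespace-only input.
    """
    if not text or not text.strip():
        raise EmptyDocumentError("cannot segment an empty document")

    paragraphs: list[tuple[Sentence, ...]] = []
    for para in re.split(r"\n\s*\n", text):
        sents = [
            Sentence(text=s, tokens=tuple(tokenize(s)))
            for s in _paragraph_sentences(para)
        ]
        sents = [s for s in sents if s.tokens]
        if sents:
            paragraphs.append(tuple(sents))

    all_tokens = [t for p in paragraphs for s in p for t in s.tokens]
    words = [t for t in all_tokens if t.is_word]
    return Document(
        raw_text=text,
        paragraphs=tuple(paragraphs),
        word_count=len(words),
        sentence_count=sum(len(p) for p in paragraphs),
        polysyllable_count=sum(1 for t in words if t.is_polysyllabic),
    )
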