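"""Resource layer for the complex-language and person-centered assessments.

A :class:`LexiconBundle` holds four resources:

frequency
    word -> commonness score on a Zipf-like scale (higher = more common).
    A word is *uncommon* when its score is strictly below
    ``uncommon_threshold`` or when it is absent from the map entirely.
thesaurus
    complex word -> list of simpler alternatives.
acronym_whitelist
    surfaces that are never flagged by the orthographic acronym rule.
person_centered
    flagged term/phrase -> preferred person-first alternative.

The package bundles small synthetic fixture lexicons (hand-curated, a few
hundred entries) so everything is testable offline; production use supplies
larger TSVs through :class:`LexiconPaths`.  File formats are documented in
the loader docstrings; ``#`` comment lines are allowed everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import LexiconError
from .textcore import Token

__all__ = [
    "LexiconBundle",
    "LexiconPaths",
    "load_bundle",
    "default_bundle",
    "write_bundle",
    "is_uncommon",
    "detect_acronym",
    "thesaurus_alternatives",
]

logger = logging.getLogger(__name__)

DEFAULT_UNCOMMON_THRESHOLD = 3.0


@dataclass
class LexiconPaths:
    """File locations for the four resources; any may be None (empty resource)."""

    frequency: Path | None = None
    thesaurus: Path | None = None
    acronyms: Path | None = None
    person_centered: Path | None = None


@dataclass
class LexiconBundle:
    frequency: dict[str, float] = field(default_factory=dict)
    uncommon_threshold: float = DEFAULT_UNCOMMON_THRESHOLD
    thesaurus: dict[str, list[str]] = field(default_factory=dict)
    acronym_whitelist: set[str] = field(default_factory=set)
    person_centered: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thesaurus = {k.casefold(): v for k, v in self.thesaurus.items()}
        self.person_centered = {k.casefold(): v for k, v in self.person_centered.items()}


def _iter_rows(text: str, name: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, stripped


def _parse_frequency(text: str, name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, row in _iter_rows(text, name):
        word, sep, score = row.partition("\t")
        if not sep:
            raise LexiconError(f"{name}:{lineno}: expected word<TAB>score, got {row!r}")
        try:
            value = float(score)
        except ValueError as exc:
            raise LexiconError(f"{name}:{lineno}: non-numeric score {score!r}") from exc
        if value < 0:
            raise LexiconError(f"{name}:{lineno}: negative score {value}")
        out[word.casefold()] = value
    return out


def _parse_thesaurus(text: str, name: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for lineno, row in _iter_rows(text, name):
        word, sep, alts = row.partition("\t")
        if not sep or not alts.strip():
            raise LexiconError(f"{name}:{lineno}: expected word<TAB>alt1|alt2, got {row!r}")
        out[word.casefold()] = [a.strip() for a in alts.split("|") if a.strip()]
    return out


def _parse_acronyms(text: str, name: str) -> set[str]:
    return {row for _, row in _iter_rows(text, name)}


def _parse_person_centered(text: str, name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, row in _iter_rows(text, name):
        phrase, sep, preferred = row.partition("\t")
        if not sep or not preferred.strip():
            raise LexiconError(
                f"{name}:{lineno}: expected phrase<TAB>preferred, got {row!r}"
            )
        key = phrase.casefold().strip()
        if key in out:
            raise LexiconError(f"{name}:{lineno}: duplicate entry {phrase!r}")
        out[key] = preferred.strip()
    return out


def load_bundle(
    paths: LexiconPaths | None = None,
    uncommon_threshold: float = DEFAULT_UNCOMMON_THRESHOLD,
) -> LexiconBundle:
    """Load a bundle from TSV files; missing files yield empty resources.

    Formats: ``frequency.tsv`` = ``word<TAB>zipf_score``; ``thesaurus.tsv`` =
    ``word<TAB>alt1|alt2|...``; ``acronyms.txt`` = one surface per line;
    ``person_centered.tsv`` = ``flagged_phrase<TAB>preferred_phrase``.
    Malformed rows raise :class:`LexiconError` naming the file and line.
    """
    if paths is None:
        return default_bundle(uncommon_threshold=uncommon_threshold)

    def read(p: Path | None, parser, label: str, empty):
        if p is None:
            logger.warning("no %s file configured; using an empty resource", label)
            return empty
        return parser(Path(p).read_text("utf-8"), str(p))

    return LexiconBundle(
        frequency=read(paths.frequency, _parse_frequency, "frequency", {}),
        uncommon_threshold=uncommon_threshold,
        thesaurus=read(paths.thesaurus, _parse_thesaurus, "thesaurus", {}),
        acronym_whitelist=read(paths.acronyms, _parse_acronyms, "acronyms", set()),
        person_centered=read(
            paths.person_centered, _parse_person_centered, "person_centered", {}
        ),
    )


def default_bundle(
    uncommon_threshold: float = DEFAULT_UNCOMMON_THRESHOLD,
) -> LexiconBundle:
    """The bundled synthetic fixture lexicons shipped with the package."""
    data = resources.files("plainlens.data")

    def read(name: str) -> str:
        return data.joinpath(name).read_text("utf-8")

    return LexiconBundle(
        frequency=_parse_frequency(read("frequency.tsv"), "frequency.tsv"),
        uncommon_threshold=uncommon_threshold,
        thesaurus=_parse_thesaurus(read("thesaurus.tsv"), "thesaurus.tsv"),
        acronym_whitelist=_parse_acronyms(read("acronyms.txt"), "acronyms.txt"),
        person_centered=_parse_person_centered(
            read("person_centered.tsv"), "person_centered.tsv"
        ),
    )


def write_bundle(bundle: LexiconBundle, directory: Path) -> LexiconPaths:
    """Serialize a bundle back to TSV files (round-trip counterpart of load)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = LexiconPaths(
        frequency=directory / "frequency.tsv",
        thesaurus=directory / "thesaurus.tsv",
        acronyms=directory / "acronyms.txt",
        person_centered=directory / "person_centered.tsv",
    )
    paths.frequency.write_text(
        "".join(f"{w}\t{s}\n" for w, s in sorted(bundle.frequency.items())), "utf-8"
    )
    paths.thesaurus.write_text(
        "".join(f"{w}\t{'|'.join(a)}\n" for w, a in sorted(bundle.thesaurus.items())),
        "utf-8",
    )
    paths.acronyms.write_text(
        "".join(f"{a}\n" for a in sorted(bundle.acronym_whitelist)), "utf-8"
    )
    paths.person_centered.write_text(
        "".join(f"{k}\t{v}\n" for k, v in sorted(bundle.person_centered.items())),
        "utf-8",
    )
    return paths


# ---------------------------------------------------------------------------
# queries

def is_uncommon(word: str, bundle: LexiconBundle) -> bool:
    """True iff the word's commonness score is below the threshold, or the
    word is absent from the frequency map (absent = uncommon by definition)."""
    score = bundle.frequency.get(word.casefold())
    if score is None:
        return True
    return score < bundle.uncommon_threshold


def detect_acronym(token: Token, bundle: LexiconBundle) -> bool:
    """Orthographic acronym rule: >= 2 uppercase letters, no lowercase,
    and not on the whitelist.  Operates on the surface form (case matters)."""
    surface = token.surface
    letters = [c for c in surface if c.isalpha()]
    if len(letters) < 2 or any(c.islower() for c in letters):
        return False
    return surface not in bundle.acronym_whitelist


def thesaurus_alternatives(word: str, bundle: LexiconBundle) -> list[str]:
    """Simpler alternatives for a word; empty list when there is no entry."""
    return list(bundle.thesaurus.get(word.casefold(), ()))
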