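"""Synthetic data generators: the package's oracle and test bed.

Two generators:

``generate_text``
    Assembles health-flavoured prose from templated active/passive
    sentence frames over annotated word pools, so the exact sentence
    count (S), polysyllable count (P), complex-word flag count, and
    passive-voice instance count are known *by construction* — an
    independent ground truth against which the parser and assessments
    can be checked exactly.  The default spec emulates the trial's
    stimulus texts: roughly 200 words at around a grade-14 reading
    level with several passive constructions and about a quarter of
    words complex.

``generate_trial``
    Draws a two-arm trial dataset (one row per participant x text) whose
    per-arm outcome means/SDs, dropout pattern, and control-arm
    contamination follow the published trial's figures by default:
    arm sizes 86/95, per-arm dropout 23/86 and 11/95, one contaminated
    control participant, and outcome distributions matching the reported
    group means and SDs.

Both generators are deterministic given their integer seed; no global
random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trial import ALL_OUTCOMES

__all__ = [
    "PoolWord",
    "TextSpec",
    "TextGroundTruth",
    "TrialSpec",
    "generate_text",
    "generate_trial",
    "DEFAULT_TRIAL_SPEC",
]


# ---------------------------------------------------------------------------
# word pools: (surface, syllables, complex-flagged under the default bundle)

@dataclass(frozen=True)
class PoolWord:
    surface: str
    syllables: int
    flagged: bool

    @property
    def is_polysyllabic(self) -> bool:
        return self.syllables >= 3


def _pool(entries, flagged):
    return tuple(PoolWord(w, s, flagged) for w, s in entries)


#: Common words of 1-2 syllables (in the bundled frequency lexicon, no
#: thesaurus entry, not acronyms).
COMMON_SHORT = _pool(
    [
        ("team", 1), ("plan", 1), ("food", 1), ("rest", 1), ("sleep", 1),
        ("pain", 1), ("nurse", 1), ("care", 1), ("home", 1), ("staff", 1),
        ("doctor", 2), ("water", 2), ("clinic", 2), ("letter", 2),
        ("morning", 2), ("window", 2), ("garden", 2), ("market", 2),
        ("ticket", 2), ("dinner", 2),
    ],
    flagged=False,
)

#: Common polysyllabic words (3+ syllables, still in the frequency lexicon).
COMMON_POLY = _pool(
    [
        ("hospital", 3), ("family", 3), ("important", 3), ("computer", 3),
        ("holiday", 3), ("remember", 3), ("tomorrow", 3), ("banana", 3),
        ("energy", 3), ("exercise", 3), ("together", 3), ("vitamin", 3),
    ],
    flagged=False,
)

#: Complex words: thesaurus keys, absent from the frequency lexicon, or
#: acronyms — all flagged by the complex-language assessment.
COMPLEX = _pool(
    [
        ("utilize", 3), ("commence", 2), ("facilitate", 4),
        ("iatrogenic", 5), ("hypertension", 4), ("analgesic", 4),
        ("prophylaxis", 4), ("comorbidity", 5), ("contraindication", 5),
        ("etiology", 4), ("MRI", 1), ("physician", 3),
    ],
    flagged=True,
)

#: Past participles used in the passive frame (common, unflagged).
PARTICIPLES = _pool(
    [
        ("given", 2), ("taken", 2), ("tested", 2), ("planned", 1),
        ("reviewed", 2), ("checked", 1), ("shown", 1), ("written", 2),
    ],
    flagged=False,
)

#: Simple past verbs used in the active frame (common, unflagged).
ACTIVE_VERBS = _pool(
    [("helped", 1), ("made", 1), ("took", 1), ("showed", 1), ("found", 1), ("kept", 1)],
    flagged=False,
)

_THE = PoolWord("the", 1, False)
_WAS = PoolWord("was", 1, False)
_BY = PoolWord("by", 1, False)

SENTENCES_PER_PARAGRAPH = 5


@dataclass(frozen=True)
class TextSpec:
    """Controls for the text generator.

    Defaults emulate the trial's stimulus texts: 13 sentences x 15 words
    (195 words), about a quarter of content slots polysyllabic or complex,
    and passives in roughly 4 of 10 sentences — which lands near a
    grade-14 readability score with ~5 passive instances.
    """

    n_sentences: int = 13
    words_per_sentence: int = 15
    polysyllable_rate: float = 0.24
    passive_rate: float = 0.38
    complex_rate: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValidationError("n_sentences must be >= 1")
        minimum = 7 if self.passive_rate > 0 else 5
        if self.words_per_sentence < minimum:
            raise ValidationError(
                f"words_per_sentence must be >= {minimum} for these rates"
            )
        for name in ("polysyllable_rate", "passive_rate", "complex_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TextGroundTruth:
    """Exact counts realized by construction."""

    sentence_count: int
    word_count: int
    polysyllable_count: int
    flagged_count: int
    passive_count: int

    @property
    def complex_pct(self) -> float:
        return 100.0 * self.flagged_count / self.word_count

    def to_json(self) -> str:
        d = asdict(self)
        d["complex_pct"] = self.complex_pct
        return json.dumps(d, indent=2)


def _draw_slot(rng: np.random.Generator, spec: TextSpec) -> PoolWord:
    if rng.random() < spec.complex_rate:
        pool = COMPLEX
    elif rng.random() < spec.polysyllable_rate:
        pool = COMMON_POLY
    else:
        pool = COMMON_SHORT
    return pool[rng.integers(len(pool))]


def generate_text(spec: TextSpec) -> tuple[str, TextGroundTruth]:
    """Generate a synthetic health-ish text plus its exact ground truth.

    Active frame:  ``The <slot> <verb> the <slot> [slots...].``
    Passive frame: ``The <slot> was <participle> by the <slot> [slots...].``

    Slot words never include be-forms or participles, so a passive frame
    contains exactly one be+participle pattern and an active frame none.
    """
    for pool, name in [
        (COMMON_SHORT, "common"), (COMMON_POLY, "polysyllabic"),
        (COMPLEX, "complex"), (PARTICIPLES, "participle"),
        (ACTIVE_VERBS, "verb"),
    ]:
        if not pool:
            raise ValidationError(f"empty {name} word pool")

    rng = np.random.default_rng(spec.seed)
    sentences: list[str] = []
    words_total = 0
    poly = 0
    flagged = 0
    passives = 0

    for _ in range(spec.n_sentences):
        is_passive = rng.random() < spec.passive_rate
        words: list[PoolWord] = []
        if is_passive:
            part = PARTICIPLES[rng.integers(len(PARTICIPLES))]
            words = [_THE, _draw_slot(rng, spec), _WAS, part, _BY, _THE,
                     _draw_slot(rng, spec)]
            passives += 1
        else:
            verb = ACTIVE_VERBS[rng.integers(len(ACTIVE_VERBS))]
            words = [_THE, _draw_slot(rng, spec), verb, _THE, _draw_slot(rng, spec)]
        while len(words) < spec.words_per_sentence:
            words.append(_draw_slot(rng, spec))

        words_total += len(words)
        poly += sum(1 for w in words if w.is_polysyllabic)
        flagged += sum(1 for w in words if w.flagged)

        surfaces = [w.surface for w in words]
        if surfaces[0].islower():
            surfaces[0] = surfaces[0].capitalize()
        sentences.append(" ".join(surfaces) + ".")

    paragraphs = [
        " ".join(sentences[i : i + SENTENCES_PER_PARAGRAPH])
        for i in range(0, len(sentences), SENTENCES_PER_PARAGRAPH)
    ]
    text = "\n\n".join(paragraphs) + "\n"
    truth = TextGroundTruth(
        sentence_count=spec.n_sentences,
        word_count=words_total,
        polysyllable_count=poly,
        flagged_count=flagged,
        passive_count=passives,
    )
    return text, truth


# ---------------------------------------------------------------------------
# trial generator

#: Published ITT group summaries used as generator defaults: mean, SD per
#: outcome for (intervention, control).
DEFAULT_OUTCOME_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "word_count": ((188.75, 23.91), (177.79, 32.40)),
    "smog": ((9.98, 2.68), (12.46, 1.59)),
    "complex_pct": ((15.19, 7.40), (22.05, 5.31)),
    "passive_count": ((2.95, 1.75), (3.90, 1.75)),
    "content_rating": ((4.9, 0.25), (4.9, 0.25)),
    "word_choice_rating": ((3.70, 0.74), (3.26, 0.58)),
    "meaning_rating": ((4.8, 0.35), (4.85, 0.30)),
}

#: Truncation bounds per outcome (declared, not inferred).
OUTCOME_BOUNDS: dict[str, tuple[float, float]] = {
    "word_count": (50.0, 400.0),
    "smog": (0.0, 20.0),
    "complex_pct": (0.0, 100.0),
    "passive_count": (0.0, 10.0),
    "content_rating": (1.0, 5.0),
    "word_choice_rating": (1.0, 5.0),
    "meaning_rating": (1.0, 5.0),
}


@dataclass(frozen=True)
class TrialSpec:
    """Two-arm trial generating parameters (intervention first, control second)."""

    n_per_arm: tuple[int, int] = (86, 95)
    outcome_params: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS)
    )
    dropout_rate: tuple[float, float] = (23 / 86, 11 / 95)
    contamination_count: int = 1
    within_participant_sd: float = 0.15  # per-text jitter, as a fraction of arm SD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_arm):
            raise ValidationError("each arm needs n >= 2")
        if any(not 0.0 <= r < 1.0 for r in self.dropout_rate):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.contamination_count < 0:
            raise ValidationError("contamination_count must be >= 0")
        for outcome, arms in self.outcome_params.items():
            if outcome not in ALL_OUTCOMES:
                raise ValidationError(f"unknown outcome {outcome!r}")
            for _, sd in arms:
                if sd <= 0:
                    raise ValidationError(f"{outcome}: SDs must be positive")


DEFAULT_TRIAL_SPEC = TrialSpec()


def generate_trial(spec: TrialSpec = DEFAULT_TRIAL_SPEC) -> pd.DataFrame:
    """Generate a long-format trial dataset (one row per participant x text).

    Participant-level outcomes are drawn from per-arm normal distributions
    truncated (by clipping) to plausible score bounds; zero-sum per-text
    jitter then spreads each participant value over the three texts so the
    participant mean is exactly the drawn value.  Noncompleters are
    flagged per-arm and carry empty per-text scores; ``contamination_count``
    control completers are marked as having used the intervention tool.
    """
    rng = np.random.default_rng(spec.seed)
    arm_names = ("intervention", "control")
    text_ids = ("text1", "text2", "text3")
    outcomes = list(spec.outcome_params)

    pieces: list[pd.DataFrame] = []
    contaminated_left = spec.contamination_count
    for arm_idx, arm in enumerate(arm_names):
        n = spec.n_per_arm[arm_idx]
        completed = rng.random(n) >= spec.dropout_rate[arm_idx]

        # per-text score = participant draw + zero-sum jitter, so the
        # participant mean over the 3 texts is exactly the drawn value
        per_text: dict[str, np.ndarray] = {}
        for outcome in outcomes:
            mean, sd = spec.outcome_params[outcome][arm_idx]
            lo, hi = OUTCOME_BOUNDS[outcome]
            vals = np.clip(rng.normal(mean, sd, size=n), lo, hi)
            jit = rng.normal(0.0, sd * spec.within_participant_sd, size=(n, 2))
            jit = np.column_stack([jit, -jit.sum(axis=1)])
            scores = vals[:, None] + jit
            scores[~completed] = np.nan
            per_text[outcome] = scores  # shape (n, 3)

        used_tool = np.zeros(n, dtype=bool)
        if arm == "control" and contaminated_left > 0:
            eligible = np.flatnonzero(completed)[:contaminated_left]
            used_tool[eligible] = True
            contaminated_left -= len(eligible)

        ids = np.array([f"{arm[:3]}{i + 1:03d}" for i in range(n)])
        block = pd.DataFrame(
            {
                "id": np.repeat(ids, 3),
                "arm": arm,
                "completed": np.repeat(completed, 3),
                "attended_training": np.repeat(
                    completed if arm == "intervention" else np.zeros(n, dtype=bool), 3
                ),
                "used_tool_in_control": np.repeat(used_tool, 3),
                "text_id": np.tile(text_ids, n),
            }
        )
        for outcome in outcomes:
            block[outcome] = per_text[outcome].reshape(-1)
        pieces.append(block)

    return pd.concat(pieces, ignore_index=True)
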