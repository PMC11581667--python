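"""Two-arm trial outcome analysis: ITT/PP set construction, effect
estimation, nonparametric tests, and acceptability scoring.

The design modelled here is a parallel two-arm trial in which every
participant revises the same three health texts and each revision receives
objective scores (word count, readability grade, complex-language
percentage, passive-voice instances) and expert ratings.  The
per-participant outcome is the mean over the three texts.

Analysis sets
-------------
ITT (intention to treat)
    every randomized participant; for a participant who did not submit a
    revision of a text, the *original* (unrevised) text's scores are
    carried forward, i.e. we assume no changes were made.
PP (per protocol)
    only participants who submitted all three revisions; intervention
    participants must additionally have attended training, and control
    participants who used the intervention tool are excluded.

Effect estimates are two-group mean differences with a pooled-variance t
confidence interval — numerically identical to the slope of a simple
linear regression of the outcome on an arm indicator.  The contrast is
reported as control minus intervention so that a positive difference
means the intervention produced simpler texts.  Highly skewed outcomes
are compared with a Mann-Whitney U test whose exact p-value is computed
by complete enumeration of the rank-sum permutation distribution
(a count dynamic program over midranks, equivalent to enumerating all
``C(n_a + n_b, n_a)`` group assignments) for small samples, and by the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .errors import DomainError, ValidationError

__all__ = [
    "OBJECTIVE_OUTCOMES",
    "RATING_OUTCOMES",
    "GroupSummary",
    "EffectEstimate",
    "OriginalTextScores",
    "ParticipantRecord",
    "TrialDataset",
    "DEFAULT_BASELINE",
    "read_trial_csv",
    "records_from_frame",
    "build_itt",
    "build_pp",
    "mean_difference",
    "mann_whitney",
    "sus_score",
    "tam_subscale_means",
    "flow_percentages",
    "outcome_table",
]

OBJECTIVE_OUTCOMES = ("word_count", "smog", "complex_pct", "passive_count")
RATING_OUTCOMES = ("content_rating", "word_choice_rating", "meaning_rating")
ALL_OUTCOMES = OBJECTIVE_OUTCOMES + RATING_OUTCOMES

#: Outcomes analyzed nonparametrically by default (median-reported,
#: heavily skewed expert ratings).
DEFAULT_SKEWED = ("content_rating", "meaning_rating")

TRIAL_CSV_COLUMNS = [
    "id", "arm", "completed", "attended_training", "used_tool_in_control",
    "text_id", *ALL_OUTCOMES,
]

ARMS = ("intervention", "control")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class EffectEstimate:
    """Mean difference (control − intervention) with pooled-t inference."""

    md: float
    ci_low: float
    ci_high: float
    cohen_d: float
    p_value: float
    n_intervention: int
    n_control: int


@dataclass(frozen=True)
class OriginalTextScores:
    """Baseline scores of the three unrevised texts, keyed by text id."""

    per_text: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.per_text) != 3:
            raise ValidationError("baseline must cover exactly 3 texts")
        for tid, scores in self.per_text.items():
            for outcome in OBJECTIVE_OUTCOMES:
                if outcome not in scores:
                    raise ValidationError(f"baseline text {tid!r} missing {outcome!r}")
                if scores[outcome] < 0:
                    raise ValidationError(f"baseline {outcome!r} must be >= 0")


def _uniform_baseline(**scores: float) -> OriginalTextScores:
    return OriginalTextScores({f"text{i}": dict(scores) for i in (1, 2, 3)})


#: Default baseline: published original-text scores applied to all 3 texts
#: (word count 195, grade 13.97, complexity 25.87%, 5 passive instances,
#: expert ratings 5.0 / 2.7 / 5.0).
DEFAULT_BASELINE = _uniform_baseline(
    word_count=195.0,
    smog=13.97,
    complex_pct=25.87,
    passive_count=5.0,
    content_rating=5.0,
    word_choice_rating=2.7,
    meaning_rating=5.0,
)


@dataclass
class ParticipantRecord:
    id: str
    arm: str
    completed: bool
    attended_training: bool = False
    used_tool_in_control: bool = False
    per_text_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    sus_items: list[int] | None = None
    tam_items: list[int] | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"participant {self.id!r}: arm must be one of {ARMS}, got {self.arm!r}"
            )
        if len(self.per_text_scores) > 3:
            raise ValidationError(f"participant {self.id!r}: more than 3 texts")
        if self.used_tool_in_control and self.arm != "control":
            raise ValidationError(
                f"participant {self.id!r}: used_tool_in_control implies control arm"
            )


@dataclass
class TrialDataset:
    records: list[ParticipantRecord]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# I/O

def read_trial_csv(path: Path | str) -> pd.DataFrame:
    """Read the long-format trial CSV (one row per participant x text)."""
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"trial CSV missing column(s): {', '.join(missing)}")
    bad_arm = ~frame["arm"].isin(ARMS)
    if bad_arm.any():
        row = int(frame.index[bad_arm][0])
        raise ValidationError(f"trial CSV row {row}: invalid arm {frame['arm'][row]!r}")
    return frame


def records_from_frame(frame: pd.DataFrame) -> TrialDataset:
    """Group the long-format frame into one :class:`ParticipantRecord` each."""
    outcomes = [o for o in ALL_OUTCOMES if o in frame.columns]
    records: list[ParticipantRecord] = []
    for pid, grp in frame.groupby("id", sort=False):
        first = grp.iloc[0]
        per_text: dict[str, dict[str, float]] = {}
        for _, row in grp.iterrows():
            scores = {o: row[o] for o in outcomes}
            if all(pd.notna(v) for v in scores.values()):
                per_text[str(row["text_id"])] = {k: float(v) for k, v in scores.items()}
        records.append(
            ParticipantRecord(
                id=str(pid),
                arm=str(first["arm"]),
                completed=bool(first["completed"]),
                attended_training=bool(first["attended_training"]),
                used_tool_in_control=bool(first["used_tool_in_control"]),
                per_text_scores=per_text,
            )
        )
    return TrialDataset(records)


# ---------------------------------------------------------------------------
# analysis sets

def _is_completer(rec: ParticipantRecord) -> bool:
    return rec.completed and len(rec.per_text_scores) == 3


def _participant_row(rec: ParticipantRecord, scores: dict[str, dict[str, float]]):
    row: dict[str, object] = {
        "id": rec.id,
        "arm": rec.arm,
        "completed": _is_completer(rec),
    }
    for outcome in ALL_OUTCOMES:
        values = [s[outcome] for s in scores.values() if outcome in s]
        row[outcome] = float(np.mean(values)) if values else float("nan")
    return row


def build_itt(
    records: list[ParticipantRecord] | TrialDataset,
    baseline: OriginalTextScores = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """ITT analysis set: one row per randomized participant.

    Original-text scores are carried forward text-wise: a participant who
    submitted no revision of a given text receives that text's baseline
    scores; completers are untouched.  The per-participant outcome is the
    mean over the three texts.
    """
    if isinstance(records, TrialDataset):
        records = records.records
    rows = []
    for rec in records:
        scores = dict(rec.per_text_scores)
        for tid, base in baseline.per_text.items():
            if tid not in scores:
                scores[tid] = dict(base)
        if len(scores) != 3:
            # submitted text ids must line up with the baseline's three ids
            extra = set(scores) - set(baseline.per_text)
            raise ValidationError(
                f"participant {rec.id!r}: text ids {sorted(extra)} not in baseline"
            )
        rows.append(_participant_row(rec, scores))
    return pd.DataFrame(rows, columns=["id", "arm", "completed", *ALL_OUTCOMES])


def build_pp(records: list[ParticipantRecord] | TrialDataset) -> pd.DataFrame:
    """PP analysis set: completers only; intervention completers must have
    attended training; contaminated control participants are dropped."""
    if isinstance(records, TrialDataset):
        records = records.records
    rows = []
    for rec in records:
        if not _is_completer(rec):
            continue
        if rec.arm == "intervention" and not rec.attended_training:
            continue
        if rec.arm == "control" and rec.used_tool_in_control:
            continue
        rows.append(_participant_row(rec, rec.per_text_scores))
    return pd.DataFrame(rows, columns=["id", "arm", "completed", *ALL_OUTCOMES])


# ---------------------------------------------------------------------------
# effect estimation

def mean_difference(
    group_a: GroupSummary | tuple,
    group_b: GroupSummary | tuple,
    alpha: float = 0.05,
    welch: bool = False,
) -> EffectEstimate:
    """Two-group mean difference ``mean_a − mean_b`` from summary statistics.

    Default inference is the pooled-variance t construction (equivalent to
    simple linear regression on an arm indicator); ``welch=True`` switches
    the CI and p-value to the Welch-Satterthwaite form.  Cohen's d is the
    classical ``md / pooled SD`` in both cases.  For outcomes where lower
    is better, pass the control summary first so ``md > 0`` reads as an
    improvement; :func:`outcome_table` handles the orientation per outcome.
    """
    a = GroupSummary(*group_a) if not isinstance(group_a, GroupSummary) else group_a
    b = GroupSummary(*group_b) if not isinstance(group_b, GroupSummary) else group_b
    if a.n < 2 or b.n < 2:
        raise DomainError("each group needs n >= 2")
    if a.sd <= 0 or b.sd <= 0:
        raise DomainError("group SDs must be positive")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")

    md = a.mean - b.mean
    sp = math.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2))
    if welch:
        se = math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
        df = (a.sd**2 / a.n + b.sd**2 / b.n) ** 2 / (
            (a.sd**2 / a.n) ** 2 / (a.n - 1) + (b.sd**2 / b.n) ** 2 / (b.n - 1)
        )
    else:
        se = sp * math.sqrt(1 / a.n + 1 / b.n)
        df = a.n + b.n - 2
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    tstat = md / se
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return EffectEstimate(
        md=md,
        ci_low=md - tcrit * se,
        ci_high=md + tcrit * se,
        cohen_d=md / sp,
        p_value=p,
        n_intervention=b.n,
        n_control=a.n,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U

EXACT_LIMIT = 400  # use exact enumeration while n_a * n_b <= this


def _exact_ranksum_pvalue(ranks2: np.ndarray, n_a: int, r2_obs: int) -> float:
    """Two-sided exact p for the rank sum of group a.

    ``ranks2`` holds doubled midranks (integers).  A count dynamic program
    builds the full permutation distribution of the group-a rank sum over
    all C(N, n_a) assignments — identical to brute-force enumeration,
    including under ties.  The permutation distribution is symmetric about
    its mean, so the two-sided p is the probability of a rank sum at least
    as far from the mean as observed.
    """
    total_sum = int(ranks2.sum())
    max_s = total_sum
    # dp[k, s] = number of k-subsets of the processed items with doubled sum s
    dp = np.zeros((n_a + 1, max_s + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1 : n_a + 1, r:] += dp[0:n_a, 0 : max_s + 1 - r]
    counts = dp[n_a]
    n_total = counts.sum()
    mean2 = n_a * total_sum / len(ranks2)  # = n_a * (N + 1) when untied
    dev = abs(r2_obs - mean2)
    s = np.arange(max_s + 1)
    tail = counts[np.abs(s - mean2) >= dev - 1e-9].sum()
    return float(tail / n_total)


def mann_whitney(
    sample_a: list[float] | np.ndarray, sample_b: list[float] | np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a) and two-sided p with midrank ties.

    Exact p by complete enumeration of the rank-sum permutation
    distribution while ``n_a * n_b <= 400``; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n_a * n_b <= EXACT_LIMIT:
        ranks2 = np.rint(ranks * 2).astype(np.int64)
        p = _exact_ranksum_pvalue(ranks2, n_a, int(round(r_a * 2)))
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            return u_a, 1.0
        z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(max(z, 0.0)))
    return u_a, min(p, 1.0)


# ---------------------------------------------------------------------------
# acceptability and flow

def sus_score(items: list[int]) -> float:
    """Standard System Usability Scale score in [0, 100].

    Ten 5-point items; odd items contribute (response − 1), even items
    (5 − response); the total is scaled by 2.5.
    """
    if len(items) != 10:
        raise ValidationError("SUS requires exactly 10 item responses")
    if any((not float(x).is_integer()) or not 1 <= x <= 5 for x in items):
        raise ValidationError("SUS responses must be integers in 1..5")
    total = sum(
        (x - 1) if i % 2 == 0 else (5 - x) for i, x in enumerate(items)
    )
    return total * 2.5


def tam_subscale_means(
    usefulness_items: list[int], ease_items: list[int]
) -> tuple[float, float]:
    """Technology-acceptance subscale means (1..5): usefulness, ease of use."""
    for items in (usefulness_items, ease_items):
        if not items or any(not 1 <= x <= 5 for x in items):
            raise ValidationError("TAM responses must be integers in 1..5")
    return (
        float(np.mean(usefulness_items)),
        float(np.mean(ease_items)),
    )


def flow_percentages(numerator: int, denominator: int) -> float:
    """Participant-flow percentage, rounded half-up to one decimal."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DomainError("numerator must be in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# outcome table

def _group_summary(values: pd.Series) -> GroupSummary:
    clean = values.dropna()
    return GroupSummary(float(clean.mean()), float(clean.std(ddof=1)), int(clean.size))


def outcome_table(
    itt_set: pd.DataFrame | None,
    pp_set: pd.DataFrame | None,
    alpha: float = 0.05,
    skewed: tuple[str, ...] = DEFAULT_SKEWED,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-outcome group summaries and effect estimates for each analysis set.

    Outcomes listed in ``skewed`` are compared by Mann-Whitney U on the raw
    participant values; the rest get pooled-t mean differences.  Contrasts
    are oriented so that a positive difference means the intervention
    improved the outcome: control − intervention for objective scores
    (lower is better), intervention − control for expert ratings (higher
    is better).  Serializes to one row per outcome x set.
    """
    blocks: list[tuple[str, pd.DataFrame]] = []
    if itt_set is not None:
        blocks.append(("ITT", itt_set))
    if pp_set is not None:
        blocks.append(("PP", pp_set))
    if not blocks:
        raise ValidationError("at least one analysis set is required")

    rows = []
    for set_name, frame in blocks:
        for outcome in ALL_OUTCOMES:
            if outcome not in frame.columns:
                raise ValidationError(
                    f"{set_name} set is missing outcome column {outcome!r}"
                )
            ctl = frame.loc[frame["arm"] == "control", outcome]
            itv = frame.loc[frame["arm"] == "intervention", outcome]
            g_ctl, g_itv = _group_summary(ctl), _group_summary(itv)
            # objective scores improve downward (control − intervention);
            # expert ratings improve upward (intervention − control)
            if outcome in RATING_OUTCOMES:
                first, second = (itv, g_itv), (ctl, g_ctl)
            else:
                first, second = (ctl, g_ctl), (itv, g_itv)
            row = {
                "analysis_set": set_name,
                "outcome": outcome,
                "mean_intervention": g_itv.mean,
                "sd_intervention": g_itv.sd,
                "n_intervention": g_itv.n,
                "mean_control": g_ctl.mean,
                "sd_control": g_ctl.sd,
                "n_control": g_ctl.n,
            }
            if outcome in skewed:
                u, p = mann_whitney(
                    first[0].dropna().to_numpy(), second[0].dropna().to_numpy()
                )
                row.update(
                    method="mann-whitney", md=np.nan, ci_low=np.nan,
                    ci_high=np.nan, cohen_d=np.nan, u_statistic=u, p_value=p,
                )
            else:
                est = mean_difference(first[1], second[1], alpha=alpha, welch=welch)
                row.update(
                    method="welch-t" if welch else "pooled-t",
                    md=est.md, ci_low=est.ci_low, ci_high=est.ci_high,
                    cohen_d=est.cohen_d, u_statistic=np.nan, p_value=est.p_value,
                )
            rows.append(row)
    return pd.DataFrame(rows)
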