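"""Analysis-set construction, effect estimation, and nonparametric tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from plainlens.errors import DomainError, ValidationError
from plainlens.trial import (
    DEFAULT_BASELINE,
    EffectEstimate,
    GroupSummary,
    OriginalTextScores,
    ParticipantRecord,
    build_itt,
    build_pp,
    flow_percentages,
    mann_whitney,
    mean_difference,
    outcome_table,
    sus_score,
    tam_subscale_means,
)

SCORES = {
    "word_count": 180.0, "smog": 9.0, "complex_pct": 14.0, "passive_count": 2.0,
    "content_rating": 5.0, "word_choice_rating": 4.0, "meaning_rating": 5.0,
}


def _record(pid="p1", arm="intervention", completed=True, training=True,
            contaminated=False, n_texts=3, smog=9.0):
    scores = dict(SCORES, smog=smog)
    return ParticipantRecord(
        id=pid, arm=arm, completed=completed, attended_training=training,
        used_tool_in_control=contaminated,
        per_text_scores={f"text{i + 1}": dict(scores) for i in range(n_texts)},
    )


class TestBuildItt:
    def test_completer_outcomes_unchanged(self):
        itt = build_itt([_record(smog=9.5)])
        assert itt.loc[0, "smog"] == pytest.approx(9.5)

    def test_noncompleter_gets_baseline_carry_forward(self):
        itt = build_itt([_record(completed=False, n_texts=0)])
        assert itt.loc[0, "smog"] == pytest.approx(13.97)
        assert itt.loc[0, "complex_pct"] == pytest.approx(25.87)

    def test_partial_submitter_imputed_text_wise(self):
        rec = _record(completed=False, n_texts=1, smog=8.0)
        itt = build_itt([rec])
        # one revised text at 8.0, two carried forward at 13.97
        assert itt.loc[0, "smog"] == pytest.approx((8.0 + 13.97 + 13.97) / 3)

    def test_all_noncompleters_force_zero_difference(self):
        recs = [
            _record(pid="a", arm="intervention", completed=False, n_texts=0),
            _record(pid="b", arm="control", completed=False, n_texts=0,
                    training=False),
        ]
        itt = build_itt(recs)
        assert itt["smog"].nunique() == 1

    def test_every_randomized_participant_included(self):
        recs = [_record(pid=f"p{i}", completed=bool(i % 2), n_texts=3 * (i % 2))
                for i in range(6)]
        assert len(build_itt(recs)) == 6

    def test_unknown_text_id_rejected(self):
        rec = _record()
        rec.per_text_scores["weird"] = rec.per_text_scores.pop("text1")
        with pytest.raises(ValidationError):
            build_itt(rec if isinstance(rec, list) else [rec])


class TestBuildPp:
    def test_control_completer_included(self):
        pp = build_pp([_record(arm="control", training=False)])
        assert len(pp) == 1

    def test_contaminated_control_excluded(self):
        pp = build_pp([_record(arm="control", training=False, contaminated=True)])
        assert len(pp) == 0

    def test_intervention_without_training_excluded(self):
        pp = build_pp([_record(training=False)])
        assert len(pp) == 0

    def test_noncompleter_excluded(self):
        pp = build_pp([_record(completed=False, n_texts=0)])
        assert len(pp) == 0

    def test_no_dropout_no_contamination_itt_equals_pp(self):
        recs = [_record(pid=f"p{i}", arm=a, training=(a == "intervention"))
                for i, a in enumerate(["intervention", "control"] * 3)]
        itt, pp = build_itt(recs), build_pp(recs)
        assert itt[["id", "smog"]].equals(pp[["id", "smog"]])


class TestMeanDifference:
    def test_identical_groups_give_zero(self):
        est = mean_difference((10.0, 2.0, 30), (10.0, 2.0, 30))
        assert est.md == 0.0
        assert est.cohen_d == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_ci_contains_md_and_is_symmetric(self):
        est = mean_difference((12.0, 2.0, 40), (10.0, 3.0, 35))
        assert est.ci_low <= est.md <= est.ci_high
        assert est.md - est.ci_low == pytest.approx(est.ci_high - est.md)

    def test_ci_width_shrinks_with_n(self):
        widths = [
            mean_difference((12.0, 2.0, n), (10.0, 2.0, n)).ci_high
            - mean_difference((12.0, 2.0, n), (10.0, 2.0, n)).ci_low
            for n in (10, 40, 160)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            mean_difference((10.0, 2.0, 1), (10.0, 2.0, 30))

    def test_equals_simple_linear_regression(self):
        """Pooled-t contrast == OLS slope on an arm indicator (independent route)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        a = rng.normal(12.0, 2.0, 40)
        b = rng.normal(10.0, 3.0, 35)
        est = mean_difference(
            (a.mean(), a.std(ddof=1), a.size), (b.mean(), b.std(ddof=1), b.size)
        )
        y = np.concatenate([a, b])
        x = sm.add_constant(np.r_[np.ones(a.size), np.zeros(b.size)])
        fit = sm.OLS(y, x).fit()
        assert est.md == pytest.approx(fit.params[1], abs=1e-10)
        assert est.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)
        lo, hi = fit.conf_int()[1]
        assert est.ci_low == pytest.approx(lo, abs=1e-8)
        assert est.ci_high == pytest.approx(hi, abs=1e-8)

    def test_welch_flag_changes_inference_not_md(self):
        pooled = mean_difference((12.0, 1.0, 50), (10.0, 4.0, 20))
        welch = mean_difference((12.0, 1.0, 50), (10.0, 4.0, 20), welch=True)
        assert pooled.md == welch.md
        assert pooled.ci_high != pytest.approx(welch.ci_high)


def _brute_force_mw(a, b):
    comb = np.concatenate([a, b])
    ranks = stats.rankdata(comb)
    n_a = len(a)
    r_obs = ranks[:n_a].sum()
    mean = n_a * (len(comb) + 1) / 2
    dev = abs(r_obs - mean)
    hits = total = 0
    for idx in itertools.combinations(range(len(comb)), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-9:
            hits += 1
    return r_obs - n_a * (n_a + 1) / 2, hits / total


class TestMannWhitney:
    def test_all_tied_gives_half_max_u(self):
        u, p = mann_whitney([2.0] * 4, [2.0] * 6)
        assert u == pytest.approx(12.0)
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        u, _ = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        u, _ = mann_whitney([3.0, 4.0], [1.0, 2.0])
        assert u == 4.0

    def test_tiny_example_exact_enumeration(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_exact_p_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n_a, n_b = rng.integers(1, 6, size=2)
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
            u_dp, p_dp = mann_whitney(list(a), list(b))
            u_bf, p_bf = _brute_force_mw(a, b)
            assert u_dp == pytest.approx(u_bf)
            assert p_dp == pytest.approx(p_bf, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 60)
        b = rng.normal(0.5, 1.0, 55)
        _, p = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])


class TestSusScore:
    def test_all_threes_give_fifty(self):
        assert sus_score([3] * 10) == pytest.approx(50.0)

    def test_best_case(self):
        assert sus_score([5, 1] * 5) == pytest.approx(100.0)

    def test_worst_case(self):
        assert sus_score([1, 5] * 5) == pytest.approx(0.0)

    @pytest.mark.parametrize("bad", [[3] * 9, [0] + [3] * 9, [6] + [3] * 9])
    def test_invalid_responses_rejected(self, bad):
        with pytest.raises(ValidationError):
            sus_score(bad)

    def test_tam_subscale_means(self):
        useful, ease = tam_subscale_means([4, 4, 3], [5, 4])
        assert useful == pytest.approx(11 / 3)
        assert ease == pytest.approx(4.5)


class TestFlowPercentages:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(147, 181, 81.2), (59, 63, 93.7), (0, 10, 0.0), (63, 86, 73.3), (84, 95, 88.4)],
    )
    def test_reported_flow_fractions(self, num, den, expected):
        assert flow_percentages(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            flow_percentages(1, 0)


class TestOutcomeTable:
    def _sets(self):
        recs = []
        rng = np.random.default_rng(5)
        for i in range(12):
            arm = "intervention" if i % 2 else "control"
            rec = _record(pid=f"p{i}", arm=arm, training=(arm == "intervention"),
                          smog=float(rng.normal(10 if arm == "intervention" else 12, 1)))
            for t in rec.per_text_scores.values():
                for outcome in t:
                    t[outcome] += float(rng.normal(0.0, 0.5))
            recs.append(rec)
        return build_itt(recs), build_pp(recs)

    def test_both_blocks_present(self):
        table = outcome_table(*self._sets())
        assert set(table["analysis_set"]) == {"ITT", "PP"}
        assert (table.groupby("analysis_set").size() == 7).all()

    def test_identical_arms_give_zero_md(self):
        recs = [_record(pid=f"p{i}", arm=a, training=(a == "intervention"))
                for i, a in enumerate(["intervention", "control"] * 4)]
        # jitter so SDs are positive but identical across arms
        for i, r in enumerate(recs):
            for t in r.per_text_scores.values():
                for outcome in t:
                    t[outcome] += (i // 2) * 0.5
        table = outcome_table(build_itt(recs), None)
        row = table[table["outcome"] == "smog"].iloc[0]
        assert row["md"] == pytest.approx(0.0)

    def test_skewed_outcomes_use_mann_whitney(self):
        table = outcome_table(*self._sets())
        skewed = table[table["outcome"] == "content_rating"]
        assert (skewed["method"] == "mann-whitney").all()
        assert skewed["u_statistic"].notna().all()

    def test_missing_outcome_column_rejected(self):
        itt, pp = self._sets()
        with pytest.raises(ValidationError):
            outcome_table(itt.drop(columns=["smog"]), pp)

    def test_serializes_one_row_per_outcome_and_set(self, tmp_path):
        table = outcome_table(*self._sets())
        path = tmp_path / "outcome_table.csv"
        table.to_csv(path, index=False)
        assert len(path.read_text().strip().splitlines()) == 1 + 14


class TestRecordValidation:
    def test_invalid_arm_rejected(self):
        with pytest.raises(ValidationError):
            ParticipantRecord(id="x", arm="placebo", completed=True)

    def test_contamination_requires_control(self):
        with pytest.raises(ValidationError):
            ParticipantRecord(
                id="x", arm="intervention", completed=True, used_tool_in_control=True
            )

    def test_baseline_must_have_three_texts(self):
        with pytest.raises(ValidationError):
            OriginalTextScores({"text1": {o: 1.0 for o in
                                          ("word_count", "smog", "complex_pct",
                                           "passive_count")}})

    def test_default_baseline_reflects_original_text_scores(self):
        scores = DEFAULT_BASELINE.per_text["text1"]
        assert scores["smog"] == 13.97
        assert scores["word_count"] == 195.0
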