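"""Metrics, confidence intervals, agreement statistics and the chi-square test."""

import math
import random

import pytest

from negex_sv import (
    ConfusionCounts,
    EngineOptions,
    GoldPair,
    Label,
    NegationDecision,
    Rationale,
    TriggerCategory,
    TriggerLexicon,
    TriggerPhrase,
    chi2_two_proportions,
    cohens_kappa,
    collapse_gold,
    confusion,
    evaluate_groups,
    metrics,
    percent_agreement,
    trigger_stats,
)
from negex_sv.engine import TriggerOccurrence

N, A = Label.NEGATED, Label.NOT_NEGATED


def make_decision(label: Label, pair_id=None, trigger_text="inte") -> NegationDecision:
    if label is N:
        occurrence = TriggerOccurrence(TriggerPhrase(trigger_text, TriggerCategory.PREN), 0, 1)
        return NegationDecision(N, (2, 3), Rationale.PRE_TRIGGER_IN_SCOPE, occurrence, 1, pair_id)
    return NegationDecision(A, (2, 3), Rationale.NO_TRIGGER, None, None, pair_id)


class TestCollapseGold:
    @pytest.mark.parametrize(
        ("raw", "expected"),
        [("negated", N), ("affirmed", A), ("ambiguous", A)],
    )
    def test_three_class_collapse(self, raw, expected):
        assert collapse_gold(raw) is expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            collapse_gold("maybe")


class TestConfusion:
    def test_perfect_predictions(self):
        decisions = [make_decision(l) for l in (N, N, A, A, A)]
        counts = confusion(decisions, [N, N, A, A, A])
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 0, 0, 3)

    def test_all_negated_predictor(self):
        decisions = [make_decision(N) for _ in range(5)]
        counts = confusion(decisions, [N, N, A, A, A])
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 3, 0, 0)

    def test_mixed_fixture_matches_hand_enumeration(self):
        predicted = [N, A, N, N, A, A, N, A, N, A]
        gold = [N, N, A, N, A, N, N, A, A, A]
        decisions = [make_decision(l) for l in predicted]
        counts = confusion(decisions, gold)
        # hand tally: positions (0,3,6) tp; (2,8) fp; (1,5) fn; (4,7,9) tn
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 2, 2, 3)
        assert counts.total == 10

    def test_id_mismatch_is_an_error(self):
        decisions = [make_decision(N, pair_id="a"), make_decision(A, pair_id="b")]
        with pytest.raises(ValueError, match="mismatch"):
            confusion(decisions, {"a": N, "c": A})


class TestMetrics:
    def test_hand_computed_ratios(self):
        report = metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert report.precision.value == pytest.approx(0.75)
        assert report.recall.value == pytest.approx(0.75)
        assert report.specificity.value == pytest.approx(5 / 6)
        assert report.npv.value == pytest.approx(5 / 6)
        for name in ("precision", "recall", "specificity", "npv"):
            metric = getattr(report, name)
            assert metric.ci_low <= metric.value <= metric.ci_high

    def test_empty_denominator_is_flagged_undefined(self):
        report = metrics(ConfusionCounts(tp=0, fp=0, fn=2, tn=3))
        assert not report.precision.defined
        assert report.npv.defined

    def test_integer_identity_precision_times_denominator(self):
        rng = random.Random(5)
        for _ in range(50):
            counts = ConfusionCounts(*(rng.randint(0, 40) for _ in range(4)))
            report = metrics(counts)
            if report.precision.defined:
                product = report.precision.value * (counts.tp + counts.fp)
                assert product == pytest.approx(counts.tp, abs=1e-9)

    def test_wald_interval_width_shrinks_with_n(self):
        wide = metrics(ConfusionCounts(tp=8, fp=2, fn=0, tn=0)).precision
        narrow = metrics(ConfusionCounts(tp=8000, fp=2000, fn=0, tn=0)).precision
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low) / 5

    def test_unknown_ci_method_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(1, 1, 1, 1), ci_method="wilson")


class TestAgreement:
    def test_percent_agreement_bounds_and_counts(self):
        assert percent_agreement([N, A, N], [N, A, N]) == 1.0
        assert percent_agreement([N, N], [A, A]) == 0.0
        assert percent_agreement(list("aaaaaaab"), list("aaaaaaaa")) == pytest.approx(7 / 8)

    def test_kappa_closed_form_two_by_two(self):
        # contingency [[20, 5], [10, 15]]: p_o = 0.70, p_e = 0.50, kappa = 0.40
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.40)

    def test_kappa_perfect_and_total_disagreement(self):
        assert cohens_kappa(["x", "y", "x"], ["x", "y", "x"]) == pytest.approx(1.0)
        # symmetric total disagreement [[0, 5], [5, 0]]
        a = ["x"] * 5 + ["y"] * 5
        b = ["y"] * 5 + ["x"] * 5
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_kappa_undefined_for_shared_constant(self):
        assert cohens_kappa(["x"] * 4, ["x"] * 4) is None

    def test_kappa_invariant_under_label_swap(self):
        rng = random.Random(11)
        a = [rng.choice("xy") for _ in range(60)]
        b = [rng.choice("xy") for _ in range(60)]
        swap = {"x": "y", "y": "x"}
        assert cohens_kappa(a, b) == pytest.approx(
            cohens_kappa([swap[l] for l in a], [swap[l] for l in b])
        )

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(3)
        a = [rng.choice("xyz") for _ in range(200)]
        b = [rng.choice("xyz") for _ in range(200)]
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestChiSquare:
    def test_closed_form_example(self):
        statistic, p_value = chi2_two_proportions(40, 50, 30, 50)
        assert statistic == pytest.approx(4.762, abs=1e-3)
        assert p_value == pytest.approx(0.029, abs=1e-3)

    def test_identical_proportions(self):
        assert chi2_two_proportions(10, 20, 10, 20) == (0.0, 1.0)

    def test_degenerate_pooled_proportion(self):
        assert chi2_two_proportions(0, 10, 0, 20) == (0.0, 1.0)
        assert chi2_two_proportions(10, 10, 20, 20) == (0.0, 1.0)

    def test_symmetry_in_the_two_samples(self):
        left = chi2_two_proportions(17, 40, 9, 30)
        right = chi2_two_proportions(9, 30, 17, 40)
        assert left == pytest.approx(right)

    def test_matches_scipy_contingency_without_correction(self):
        from scipy.stats import chi2_contingency

        for x1, n1, x2, n2 in [(40, 50, 30, 50), (5, 30, 12, 25), (1, 10, 9, 10)]:
            statistic, p_value = chi2_two_proportions(x1, n1, x2, n2)
            ref = chi2_contingency([[x1, n1 - x1], [x2, n2 - x2]], correction=False)
            assert statistic == pytest.approx(ref.statistic)
            assert p_value == pytest.approx(ref.pvalue)

    def test_significance_threshold_at_one_percent(self):
        rng = random.Random(9)
        for _ in range(50):
            n1, n2 = rng.randint(5, 80), rng.randint(5, 80)
            x1, x2 = rng.randint(0, n1), rng.randint(0, n2)
            statistic, p_value = chi2_two_proportions(x1, n1, x2, n2)
            assert (p_value < 0.01) == (statistic > 6.635) or math.isclose(statistic, 6.635)


class TestTriggerStats:
    def test_hand_counted_precision(self):
        decisions = [make_decision(N, trigger_text="ingen") for _ in range(4)]
        gold = [N, N, N, A]
        (stats,) = trigger_stats(decisions, gold)
        assert (stats.phrase, stats.occurrences, stats.correct) == ("ingen", 4, 3)
        assert stats.precision == pytest.approx(0.75)

    def test_non_deciding_triggers_are_absent(self):
        decisions = [make_decision(A), make_decision(N, trigger_text="aldrig")]
        stats = trigger_stats(decisions, [A, N])
        assert [s.phrase for s in stats] == ["aldrig"]
        assert stats[0].precision == 1.0

    def test_sorted_by_precision_then_occurrences(self):
        decisions = (
            [make_decision(N, trigger_text="aldrig")] * 3
            + [make_decision(N, trigger_text="ingen")] * 4
            + [make_decision(N, trigger_text="inte")] * 4
        )
        gold = [N] * 3 + [N, N, N, A] + [N, A, A, A]
        stats = trigger_stats(decisions, gold)
        assert [s.phrase for s in stats] == ["aldrig", "ingen", "inte"]


class TestEvaluateGroups:
    def small_corpus(self):
        with_trigger = [
            GoldPair("p1", "inga tecken på astma", "astma", "negated"),
            GoldPair("p2", "ingen feber", "feber", "negated"),
            GoldPair("p3", "troligen ingen uppenbar astma", "astma", "ambiguous"),
            GoldPair("p4", "inte säkert om feber", "feber", "affirmed"),
            GoldPair("p5", "astma besvär kvar ej besvärsfri", "astma", "affirmed"),
        ]
        without_trigger = [
            GoldPair("p6", "pat mår bra", "bra", "affirmed"),
            GoldPair("p7", "viss feber idag", "feber", "affirmed"),
        ]
        return with_trigger, without_trigger

    def test_metrics_equal_independent_hand_computation(self, refined_lexicon):
        from negex_sv import classify

        with_trigger, without_trigger = self.small_corpus()
        options = EngineOptions(profile="refined")
        result = evaluate_groups(with_trigger, without_trigger, refined_lexicon, options)

        # independent tally with plain loops over the library's decisions
        tp = fp = fn = tn = 0
        for pair in with_trigger:
            predicted = classify(pair.sentence_text, pair.proposition, refined_lexicon, options)
            is_negated = predicted.label is N
            actually = pair.label == "negated"
            tp += is_negated and actually
            fp += is_negated and not actually
            fn += (not is_negated) and actually
            tn += (not is_negated) and not actually
        counts = result.with_trigger.counts
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)
        assert result.with_trigger.report.precision.value == pytest.approx(tp / (tp + fp))

    def test_oracle_predictor_scores_perfectly(self, refined_lexicon):
        # every pair is constructed so that the engine's decision equals the
        # collapsed gold: all defined metrics must be 1.0
        with_trigger = [
            GoldPair("p1", "inga tecken på astma", "astma", "negated"),
            GoldPair("p2", "ingen feber", "feber", "negated"),
            GoldPair("p4", "inte säkert om feber", "feber", "affirmed"),
        ]
        result = evaluate_groups(with_trigger, [], refined_lexicon, EngineOptions(profile="refined"))
        report = result.with_trigger.report
        assert report.precision.value == report.recall.value == 1.0
        assert report.specificity.value == report.npv.value == 1.0

    def test_trigger_free_group_reports_npv_only(self, refined_lexicon):
        _, without_trigger = self.small_corpus()
        result = evaluate_groups([], without_trigger, refined_lexicon)
        report = result.without_trigger.report
        assert report.npv.value == 1.0  # zero gold negations, zero predictions
        assert not report.precision.defined
        # empty with-trigger group is flagged, not an error
        assert not result.with_trigger.report.recall.defined
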