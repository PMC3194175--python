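"""Evaluation harness: metrics, per-trigger statistics, agreement, chi-square.

The evaluation design mirrors the classic two-group negation-detection
study: gold annotations use three classes (affirmed / negated / ambiguous),
the affirmed and ambiguous classes collapse into *not negated* before
scoring, and the system is scored separately on sentences that contain
trigger phrases (precision, recall, specificity, NPV, each with a 95%
Wald confidence interval) and on sentences without triggers (NPV only).
Per-trigger frequency and precision tables, two-rater percent agreement and
Cohen's kappa, and a Pearson chi-square comparison of two proportions
complete the harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats as _stats

from .engine import EngineOptions, Label, NegationDecision, classify
from .lexicon import TriggerLexicon

__all__ = [
    "GOLD_LABELS",
    "GoldAnnotation",
    "GoldPair",
    "ConfusionCounts",
    "Metric",
    "MetricReport",
    "TriggerUsageStats",
    "GroupEvaluation",
    "EvaluationResult",
    "collapse_gold",
    "confusion",
    "metrics",
    "trigger_stats",
    "percent_agreement",
    "cohens_kappa",
    "chi2_two_proportions",
    "evaluate_groups",
]

GOLD_LABELS = ("affirmed", "negated", "ambiguous")


@dataclass(frozen=True)
class GoldAnnotation:
    """One rater's three-class label for one pair."""

    pair_id: str
    label: str
    rater_id: str = "r1"

    def __post_init__(self) -> None:
        if self.label not in GOLD_LABELS:
            raise ValueError(f"unknown gold label {self.label!r}; expected one of {GOLD_LABELS}")


@dataclass(frozen=True)
class GoldPair:
    """A gold-annotated (sentence, proposition) pair ready for evaluation."""

    pair_id: str
    sentence_text: str
    proposition: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in GOLD_LABELS:
            raise ValueError(f"unknown gold label {self.label!r}; expected one of {GOLD_LABELS}")


def collapse_gold(label: str) -> Label:
    """Collapse the three-class annotation into negated / not negated."""
    if label == "negated":
        return Label.NEGATED
    if label in ("affirmed", "ambiguous"):
        return Label.NOT_NEGATED
    raise ValueError(f"unknown gold label {label!r}; expected one of {GOLD_LABELS}")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with *negated* as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _collapsed_gold_for(
    decisions: Sequence[NegationDecision],
    gold: Sequence[Label | str] | Mapping[str, Label | str],
) -> list[Label]:
    """Align gold labels to decisions, by pair id when gold is a mapping."""
    if isinstance(gold, Mapping):
        ids = [d.pair_id for d in decisions]
        if any(i is None for i in ids):
            raise ValueError("decisions must carry pair ids to align against a gold mapping")
        missing = [i for i in ids if i not in gold]
        extra = sorted(set(gold) - set(ids))
        if missing or extra:
            raise ValueError(f"gold/decision id mismatch; missing={missing!r} extra={extra!r}")
        aligned: Sequence[Label | str] = [gold[i] for i in ids]
    else:
        if len(gold) != len(decisions):
            raise ValueError(
                f"length mismatch: {len(decisions)} decisions vs {len(gold)} gold labels"
            )
        aligned = gold
    return [lab if isinstance(lab, Label) else Label(lab) for lab in aligned]


def confusion(
    decisions: Sequence[NegationDecision],
    gold: Sequence[Label | str] | Mapping[str, Label | str],
) -> ConfusionCounts:
    """Tally predictions against collapsed gold labels."""
    labels = _collapsed_gold_for(decisions, gold)
    tp = fp = fn = tn = 0
    for decision, truth in zip(decisions, labels):
        predicted = decision.label is Label.NEGATED
        actual = truth is Label.NEGATED
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass(frozen=True)
class Metric:
    """A proportion with its 95% CI; ``value is None`` when undefined."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class MetricReport:
    """Precision / recall (sensitivity) / specificity / NPV with 95% CIs."""

    precision: Metric
    recall: Metric
    specificity: Metric
    npv: Metric


def _wald(numerator: int, denominator: int) -> Metric:
    if denominator == 0:
        return Metric(None, None, None, 0)
    p = numerator / denominator
    z = float(_stats.norm.ppf(0.975))
    half = z * math.sqrt(p * (1.0 - p) / denominator)
    return Metric(p, max(0.0, p - half), min(1.0, p + half), denominator)


def metrics(counts: ConfusionCounts, ci_method: str = "wald") -> MetricReport:
    """Point estimates and 95% CIs from confusion counts.

    Only the Wald interval (normal approximation on the point estimate) is
    built in; a metric whose denominator is zero is reported as undefined.
    """
    if ci_method != "wald":
        raise ValueError(f"unknown ci_method {ci_method!r}; only 'wald' is built in")
    return MetricReport(
        precision=_wald(counts.tp, counts.tp + counts.fp),
        recall=_wald(counts.tp, counts.tp + counts.fn),
        specificity=_wald(counts.tn, counts.tn + counts.fp),
        npv=_wald(counts.tn, counts.tn + counts.fn),
    )


@dataclass(frozen=True)
class TriggerUsageStats:
    """Frequency and precision of one deciding trigger phrase."""

    phrase: str
    occurrences: int
    correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.correct <= self.occurrences):
            raise ValueError("need 0 <= correct <= occurrences")

    @property
    def precision(self) -> float:
        return self.correct / self.occurrences


def trigger_stats(
    decisions: Sequence[NegationDecision],
    gold: Sequence[Label | str] | Mapping[str, Label | str],
) -> list[TriggerUsageStats]:
    """Per-trigger frequency and precision over negated decisions.

    Each negated decision is attributed to exactly one deciding trigger (the
    engine's nearest winner); not-negated decisions contribute nothing.
    Sorted by precision, then occurrences, both descending.
    """
    labels = _collapsed_gold_for(decisions, gold)
    tallies: dict[str, list[int]] = {}
    for decision, truth in zip(decisions, labels):
        if decision.label is not Label.NEGATED:
            continue
        assert decision.trigger is not None
        phrase = decision.trigger.phrase.text
        occurrences, correct = tallies.setdefault(phrase, [0, 0])
        tallies[phrase][0] = occurrences + 1
        tallies[phrase][1] = correct + (1 if truth is Label.NEGATED else 0)
    result = [TriggerUsageStats(p, occ, cor) for p, (occ, cor) in tallies.items()]
    result.sort(key=lambda s: (-s.precision, -s.occurrences, s.phrase))
    return result


def percent_agreement(a: Sequence[object], b: Sequence[object]) -> float:
    """Fraction of positions where two raters' labels agree."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("label lists must be non-empty")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def cohens_kappa(a: Sequence[object], b: Sequence[object]) -> float | None:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the product of the raters' marginal
    label proportions. Returns ``None`` (undefined) when both raters use a
    single shared constant label.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("label lists must be non-empty")
    n = len(a)
    labels = sorted(set(a) | set(b), key=repr)
    if len(labels) < 2:
        return None
    p_o = sum(x == y for x, y in zip(a, b)) / n
    counts_a = {lab: sum(x == lab for x in a) for lab in labels}
    counts_b = {lab: sum(x == lab for x in b) for lab in labels}
    p_e = sum(counts_a[lab] * counts_b[lab] for lab in labels) / (n * n)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def chi2_two_proportions(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square test of two proportions (1 df, no continuity correction).

    Returns ``(statistic, p_value)``; a degenerate table whose pooled
    proportion is 0 or 1 yields ``(0.0, 1.0)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("success counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    p1, p2 = x1 / n1, x2 / n2
    statistic = (p1 - p2) ** 2 / (pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    p_value = float(_stats.chi2.sf(statistic, df=1))
    return statistic, p_value


@dataclass(frozen=True)
class GroupEvaluation:
    """Counts plus the metric report for one sentence group."""

    counts: ConfusionCounts
    report: MetricReport
    decisions: tuple[NegationDecision, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class EvaluationResult:
    """Two-group evaluation output: full metrics, NPV-only group, trigger table."""

    with_trigger: GroupEvaluation
    without_trigger: GroupEvaluation
    triggers: tuple[TriggerUsageStats, ...]


def _run_group(
    pairs: Sequence[GoldPair], lexicon: TriggerLexicon, options: EngineOptions
) -> tuple[list[NegationDecision], list[Label]]:
    decisions = [
        classify(
            pair.sentence_text,
            pair.proposition,
            lexicon,
            options,
            sentence_id=pair.pair_id,
            pair_id=pair.pair_id,
        )
        for pair in pairs
    ]
    gold = [collapse_gold(pair.label) for pair in pairs]
    return decisions, gold


def evaluate_groups(
    with_trigger: Sequence[GoldPair],
    without_trigger: Sequence[GoldPair],
    lexicon: TriggerLexicon,
    options: EngineOptions | None = None,
) -> EvaluationResult:
    """Run the engine over both sentence groups and score it.

    The trigger-bearing group gets all four metrics; the trigger-free group
    is reported as NPV only (by construction nearly every prediction there
    is *not negated*, so the other denominators are tiny or empty). The
    per-trigger table pools negated decisions from both groups. Empty
    groups yield undefined metrics rather than an error.
    """
    options = options or EngineOptions()
    d1, g1 = _run_group(with_trigger, lexicon, options)
    d2, g2 = _run_group(without_trigger, lexicon, options)
    counts1 = confusion(d1, g1)
    counts2 = confusion(d2, g2)
    report1 = metrics(counts1)
    undefined = Metric(None, None, None, 0)
    report2 = MetricReport(
        precision=undefined,
        recall=undefined,
        specificity=undefined,
        npv=metrics(counts2).npv,
    )
    stats = trigger_stats(d1 + d2, g1 + g2)
    return EvaluationResult(
        with_trigger=GroupEvaluation(counts1, report1, tuple(d1)),
        without_trigger=GroupEvaluation(counts2, report2, tuple(d2)),
        triggers=tuple(stats),
    )
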