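"""Seeded synthetic corpus generator with derivable gold labels.

Real Swedish clinical corpora are access-restricted, so every component of
this package is exercised on generated clinical-style sentences instead.
The generator emulates the two-group evaluation design (trigger-bearing vs.
trigger-free sentences; affirmed / negated / ambiguous gold classes) with
template sentences: filler tokens around an optional trigger phrase and a
proposition placed at a sampled word distance, optionally inside a compound
token or shadowed by a pseudo-negation, a scope-cutting conjunction, or an
uncertainty hedge.

Gold labels are derivable by construction: a record is gold-negated exactly
when an unmasked trigger lies within the configured scope window of the
proposition, with respect to the lexicon and engine options the corpus was
generated under. Ambiguous records carry hedges, conditional clauses or
past-condition markers — the phrasing classes that make human annotation
hard — and are collapsed into *not negated* at scoring time, which is what
produces realistic false positives. Every non-ambiguous record is verified
against the independent :func:`oracle_label` at generation time.

Fixtures are structural, not linguistic, stand-ins for clinical text.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .engine import EngineOptions, SentenceRecord, find_proposition_spans, find_triggers, tokenize
from .evaluation import GoldPair
from .lexicon import TriggerCategory, TriggerLexicon
from .termlist import PropositionTerm

__all__ = [
    "FixtureConfig",
    "FixtureRecord",
    "FixtureCorpus",
    "DEFAULT_TERMS",
    "generate",
    "oracle_label",
    "default_terms",
]

# Neutral clinical-style filler vocabulary. Nothing here is a trigger token,
# a conjunction, a hedge, or a substring-superstring of a default term.
_FILLERS = (
    "pat", "mår", "bra", "idag", "vid", "besök", "kontroll", "bedömning",
    "status", "stabil", "opåverkad", "hemgång", "planeras", "uppföljning",
    "enligt", "anamnes", "prover", "togs", "igår", "kliniskt", "lugn",
    "samtal", "väsentligen", "rtg", "svar", "avvaktas",
)

_HEDGES = ("möjligen", "eventuellt", "oklart", "kanske", "troligen", "misstänkt")
_PAST_MARKERS = ("tidigare", "förr")
_CONDITIONAL_OPENERS = ("om",)
_CONDITIONAL_TAILS = (("skulle", "uppstå",), ("skulle", "förvärras",))
_ICKE_ADJECTIVES = ("allergisk", "infektiös", "specifik")
_COMPOUND_SUFFIXES = ("besvär", "symtom", "tendens", "anfall")

DEFAULT_TERMS = ("astma", "pneumoni", "hosta", "feber", "yrsel", "anemi", "diabetes")

_DEFAULT_DISTANCE_WEIGHTS: Mapping[int, float] = {
    1: 0.30, 2: 0.22, 3: 0.16, 4: 0.10, 5: 0.07, 6: 0.05, 7: 0.06, 8: 0.04,
}


def default_terms() -> list[PropositionTerm]:
    """The packaged synthetic proposition list."""
    return [PropositionTerm(t) for t in DEFAULT_TERMS]


@dataclass(frozen=True)
class FixtureConfig:
    """Generation conditions for one synthetic corpus.

    The defaults emulate the published two-group test design: 900 pairs
    with roughly a 0.31 overall gold-negated rate (the published corpus had
    281 negated of 900), pseudo-negations and ambiguous phrasings at small
    rates, a compound-embedded proposition in 15% of records, and a word
    distance distribution concentrated near the trigger but with mass
    beyond the six-word window.
    """

    n_sentences: int = 900
    p_negated: float = 0.31
    p_pseudo: float = 0.05
    p_compound: float = 0.15
    p_ambiguous: float = 0.12
    distance_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_DISTANCE_WEIGHTS)
    )
    seed: int = 0
    scope_limit: int = 6
    #: share of ambiguous records carrying an in-window trigger (the class
    #: that yields realistic false positives after collapsing)
    ambiguous_trigger_share: float = 0.40
    #: sub-styles of plain-affirmed records (weights, renormalized)
    affirmed_style_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "plain": 0.44,
            "benign_trigger": 0.22,
            "out_of_scope": 0.16,
            "conjunction_cut": 0.12,
            "icke": 0.03,
            "utan": 0.03,
        }
    )
    #: probability that the simulated second rater flips a trigger-group
    #: record's collapsed class (0.125 reproduces the published agreement
    #: regime: ~87.5% agreement, kappa ~0.75 at ~0.48 prevalence)
    p_rater_flip: float = 0.125

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")
        for name in ("p_negated", "p_pseudo", "p_compound", "p_ambiguous", "p_rater_flip"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.p_negated + self.p_pseudo + self.p_ambiguous > 1.0:
            raise ValueError("p_negated + p_pseudo + p_ambiguous must not exceed 1")
        weights = dict(self.distance_distribution)
        if not weights or any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise ValueError("distance weights must be non-negative and not all zero")
        if any(d < 1 for d in weights):
            raise ValueError("distances must be >= 1")
        if self.scope_limit < 1:
            raise ValueError("scope_limit must be >= 1")


@dataclass(frozen=True)
class FixtureRecord:
    """One generated (sentence, proposition) pair with bookkeeping."""

    pair_id: str
    text: str
    proposition: str
    prop_span: tuple[int, int]
    gold: str  # affirmed | negated | ambiguous
    rater2: str
    group: str  # with_trigger | without_trigger
    construction: str
    distance: int | None = None
    trigger_text: str | None = None
    compound: bool = False


@dataclass(frozen=True)
class FixtureCorpus:
    """A generated corpus plus the conditions it was generated under."""

    records: tuple[FixtureRecord, ...]
    config: FixtureConfig
    options: EngineOptions

    def pair_rows(self) -> list[tuple[str, str, str]]:
        return [(r.pair_id, r.text, r.proposition) for r in self.records]

    def gold_rows(self, rater: int = 1) -> list[tuple[str, str, str, str]]:
        return [
            (r.pair_id, r.text, r.proposition, r.gold if rater == 1 else r.rater2)
            for r in self.records
        ]

    def gold_pairs(self, rater: int = 1, group: str | None = None) -> list[GoldPair]:
        return [
            GoldPair(r.pair_id, r.text, r.proposition, r.gold if rater == 1 else r.rater2)
            for r in self.records
            if group is None or r.group == group
        ]

    def write_pair_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(row) for row in self.pair_rows()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def write_gold_tsv(self, path: str | Path, rater: int = 1) -> None:
        lines = ["\t".join(row) for row in self.gold_rows(rater)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _sample_distance(
    rng: random.Random, weights: Mapping[int, float], lo: int, hi: int
) -> int:
    choices = [(d, w) for d, w in sorted(weights.items()) if lo <= d <= hi and w > 0]
    if not choices:
        return lo
    distances, mass = zip(*choices)
    return rng.choices(distances, weights=mass, k=1)[0]


class _Builder:
    """Stateful helper assembling one corpus; not part of the public API."""

    def __init__(
        self,
        config: FixtureConfig,
        lexicon: TriggerLexicon,
        terms: Sequence[PropositionTerm],
        options: EngineOptions,
    ) -> None:
        self.config = config
        self.lexicon = lexicon
        self.options = options
        self.rng = random.Random(config.seed)
        self.terms = list(terms)

        lexicon_tokens = {tok for phrase in lexicon for tok in phrase.tokens}
        term_surfaces = [t.surface for t in self.terms]
        self.fillers = [
            w
            for w in _FILLERS
            if w not in lexicon_tokens
            and not any(s in w or w in s for s in term_surfaces)
        ]
        if len(self.fillers) < 5:
            raise ValueError("lexicon/terms leave too few safe filler words")

        self.pren = [
            p
            for p in lexicon.by_category(TriggerCategory.PREN)
            if p.text != "icke"
        ]
        self.post = list(lexicon.by_category(TriggerCategory.POST))
        self.pseu = list(lexicon.by_category(TriggerCategory.PSEU))
        self.conj = [p for p in lexicon.by_category(TriggerCategory.CONJ)]
        if config.p_negated > 0 and not (self.pren or self.post):
            raise ValueError("p_negated > 0 requires PREN or POST entries in the lexicon")
        if config.p_pseudo > 0 and not self.pseu:
            raise ValueError("p_pseudo > 0 requires PSEU entries in the lexicon")

    # -- small sampling helpers -------------------------------------------
    def some_fillers(self, lo: int, hi: int) -> list[str]:
        return [self.rng.choice(self.fillers) for _ in range(self.rng.randint(lo, hi))]

    def proposition_word(self, term: PropositionTerm) -> tuple[str, bool]:
        if len(term.tokens) == 1 and self.rng.random() < self.config.p_compound:
            return term.surface + self.rng.choice(_COMPOUND_SUFFIXES), True
        return term.surface, False

    def pick_trigger(self) -> tuple[tuple[str, ...], str]:
        """An unmasked negating trigger: (tokens, side)."""
        use_post = bool(self.post) and (not self.pren or self.rng.random() < 0.25)
        if use_post:
            return self.rng.choice(self.post).tokens, "post"
        return self.rng.choice(self.pren).tokens, "pre"

    def maybe_punctuate(self, words: list[str]) -> list[str]:
        out = list(words)
        if out and self.rng.random() < 0.5:
            out[-1] = out[-1] + "."
        return out

    # -- constructions ------------------------------------------------------
    def build(self, index: int) -> FixtureRecord:
        cfg, rng = self.config, self.rng
        term = rng.choice(self.terms)
        prop_word, compound = self.proposition_word(term)
        u = rng.random()
        if u < cfg.p_negated:
            record = self._negated(index, term, prop_word, compound)
        elif u < cfg.p_negated + cfg.p_pseudo:
            record = self._pseudo(index, term, prop_word, compound)
        elif u < cfg.p_negated + cfg.p_pseudo + cfg.p_ambiguous:
            record = self._ambiguous(index, term, prop_word, compound)
        else:
            record = self._affirmed(index, term, prop_word, compound)
        return self._finalize(record)

    def _make(
        self,
        index: int,
        words: list[str],
        term: PropositionTerm,
        prop_word: str,
        gold: str,
        group: str,
        construction: str,
        distance: int | None = None,
        trigger_text: str | None = None,
        compound: bool = False,
    ) -> FixtureRecord:
        text = " ".join(self.maybe_punctuate(words))
        sentence = tokenize(text)
        spans = find_proposition_spans(sentence, term.surface)
        if not spans:
            raise RuntimeError(f"generator bug: proposition lost in {text!r}")
        return FixtureRecord(
            pair_id=f"s{index:05d}",
            text=text,
            proposition=term.surface,
            prop_span=spans[0],
            gold=gold,
            rater2=gold,
            group=group,
            construction=construction,
            distance=distance,
            trigger_text=trigger_text,
            compound=compound,
        )

    def _negated(self, index, term, prop_word, compound) -> FixtureRecord:
        cfg, rng = self.config, self.rng
        trigger, side = self.pick_trigger()
        d = _sample_distance(rng, cfg.distance_distribution, 1, cfg.scope_limit)
        between = [rng.choice(self.fillers) for _ in range(d - 1)]
        if between and rng.random() < 0.2:
            i = rng.randrange(len(between))
            between[i] = between[i] + ","  # punctuation must not count toward the window
        prelude = self.some_fillers(1, 3)
        tail = self.some_fillers(0, 2)
        if side == "pre":
            words = prelude + list(trigger) + between + [prop_word] + tail
        else:
            words = prelude + [prop_word] + between + list(trigger) + tail
        return self._make(
            index, words, term, prop_word, "negated", "with_trigger",
            f"negated_{side}", distance=d, trigger_text=" ".join(trigger), compound=compound,
        )

    def _pseudo(self, index, term, prop_word, compound) -> FixtureRecord:
        rng = self.rng
        pseudo = rng.choice(self.pseu)
        words = (
            self.some_fillers(1, 2)
            + list(pseudo.tokens)
            + self.some_fillers(0, 2)
            + [prop_word]
            + self.some_fillers(0, 1)
        )
        return self._make(
            index, words, term, prop_word, "affirmed", "with_trigger",
            "pseudo", trigger_text=pseudo.text, compound=compound,
        )

    def _ambiguous(self, index, term, prop_word, compound) -> FixtureRecord:
        cfg, rng = self.config, self.rng
        if rng.random() < cfg.ambiguous_trigger_share and self.pren:
            trigger = rng.choice(self.pren).tokens
            if cfg.scope_limit >= 2:
                d = rng.randint(2, cfg.scope_limit)
                between = [rng.choice(_HEDGES)] + [
                    rng.choice(self.fillers) for _ in range(d - 2)
                ]
                words = self.some_fillers(1, 2) + list(trigger) + between + [prop_word]
            else:
                d = 1
                words = (
                    self.some_fillers(1, 2) + list(trigger) + [prop_word] + [rng.choice(_HEDGES)]
                )
            return self._make(
                index, words, term, prop_word, "ambiguous", "with_trigger",
                "ambiguous_hedge_trigger", distance=d,
                trigger_text=" ".join(trigger), compound=compound,
            )
        style = rng.choices(("hedge", "past", "conditional"), weights=(0.45, 0.35, 0.2))[0]
        if style == "hedge":
            words = self.some_fillers(1, 2) + [rng.choice(_HEDGES), prop_word] + self.some_fillers(0, 2)
        elif style == "past":
            words = self.some_fillers(0, 2) + [rng.choice(_PAST_MARKERS), prop_word] + self.some_fillers(0, 2)
        else:
            words = (
                [rng.choice(_CONDITIONAL_OPENERS), prop_word]
                + list(rng.choice(_CONDITIONAL_TAILS))
                + self.some_fillers(0, 1)
            )
        return self._make(
            index, words, term, prop_word, "ambiguous", "without_trigger",
            f"ambiguous_{style}", compound=compound,
        )

    def _affirmed(self, index, term, prop_word, compound) -> FixtureRecord:
        cfg, rng = self.config, self.rng
        weights = dict(cfg.affirmed_style_weights)
        if not self.pren:
            for style in ("benign_trigger", "out_of_scope", "conjunction_cut", "icke", "utan"):
                weights[style] = 0.0
        if not self.conj or not cfg.distance_distribution or not self.options.use_conjunction_cut:
            weights["conjunction_cut"] = 0.0
        if cfg.scope_limit < 2:
            weights["conjunction_cut"] = 0.0
        if ("icke", TriggerCategory.PREN) in self.lexicon:
            # with "icke" as a live trigger the construction would derive as
            # negated; only trigger-free lexicons can host it as affirmed
            weights["icke"] = 0.0
        if self.options.profile != "refined" or ("utan", TriggerCategory.PREN) not in self.lexicon:
            weights["utan"] = 0.0
        if not any(weights.values()):
            weights = {"plain": 1.0}
        styles, mass = zip(*sorted(weights.items()))
        style = rng.choices(styles, weights=mass, k=1)[0]

        if style == "plain":
            words = self.some_fillers(1, 3) + [prop_word] + self.some_fillers(0, 3)
            return self._make(
                index, words, term, prop_word, "affirmed", "without_trigger",
                "affirmed_plain", compound=compound,
            )
        if style == "benign_trigger":
            trigger = rng.choice(self.pren).tokens
            words = (
                self.some_fillers(0, 2) + [prop_word] + self.some_fillers(0, 2)
                + list(trigger) + self.some_fillers(1, 2)
            )
            return self._make(
                index, words, term, prop_word, "affirmed", "with_trigger",
                "affirmed_benign_trigger", trigger_text=" ".join(trigger), compound=compound,
            )
        if style == "out_of_scope":
            trigger = rng.choice(self.pren).tokens
            d = _sample_distance(
                rng, cfg.distance_distribution, cfg.scope_limit + 1, max(cfg.distance_distribution)
            )
            d = max(d, cfg.scope_limit + 1)
            between = [rng.choice(self.fillers) for _ in range(d - 1)]
            words = self.some_fillers(0, 1) + list(trigger) + between + [prop_word]
            return self._make(
                index, words, term, prop_word, "affirmed", "with_trigger",
                "affirmed_out_of_scope", distance=d,
                trigger_text=" ".join(trigger), compound=compound,
            )
        if style == "conjunction_cut":
            trigger = rng.choice(self.pren).tokens
            d = rng.randint(2, cfg.scope_limit)
            between = [rng.choice(self.fillers) for _ in range(d - 1)]
            between[rng.randrange(len(between))] = rng.choice(self.conj).text
            words = self.some_fillers(0, 2) + list(trigger) + between + [prop_word]
            return self._make(
                index, words, term, prop_word, "affirmed", "with_trigger",
                "affirmed_conjunction_cut", distance=d,
                trigger_text=" ".join(trigger), compound=compound,
            )
        if style == "icke":
            words = (
                self.some_fillers(0, 2)
                + ["icke", rng.choice(_ICKE_ADJECTIVES), prop_word]
                + self.some_fillers(0, 1)
            )
            return self._make(
                index, words, term, prop_word, "affirmed", "without_trigger",
                "affirmed_icke", compound=compound,
            )
        # style == "utan": an "inte ... utan X" contrast where the distant
        # "inte" is out of window and the refined rule unmasks nothing
        between = [rng.choice(self.fillers) for _ in range(self.config.scope_limit)]
        words = self.some_fillers(0, 1) + ["inte"] + between + ["utan", prop_word]
        return self._make(
            index, words, term, prop_word, "affirmed", "with_trigger",
            "affirmed_utan", trigger_text="utan", compound=compound,
        )

    # -- verification -------------------------------------------------------
    def _finalize(self, record: FixtureRecord) -> FixtureRecord:
        sentence = tokenize(record.text, id=record.pair_id)
        occurrences = find_triggers(sentence, self.lexicon)
        relevant = {TriggerCategory.PREN, TriggerCategory.POST, TriggerCategory.PSEU}
        observed_group = (
            "with_trigger"
            if any(o.category in relevant for o in occurrences)
            else "without_trigger"
        )
        if observed_group != record.group:
            raise RuntimeError(
                f"generator bug: group bookkeeping mismatch for {record.text!r}"
            )
        if record.gold != "ambiguous":
            expected = "negated" if record.gold == "negated" else "not_negated"
            observed = oracle_label(sentence, record.prop_span, self.lexicon, self.options)
            if observed != expected:
                raise RuntimeError(
                    f"generator bug: gold {record.gold!r} but oracle says "
                    f"{observed!r} for {record.text!r}"
                )
        # simulated second rater: disagreements concentrate on the
        # negated-vs-ambiguous boundary, in the trigger group only
        rater2 = record.gold
        if record.group == "with_trigger" and self.rng.random() < self.config.p_rater_flip:
            if record.gold == "negated":
                rater2 = "ambiguous" if self.rng.random() < 0.72 else "affirmed"
            else:
                rater2 = "negated"
        return replace(record, rater2=rater2)


def generate(
    config: FixtureConfig,
    lexicon: TriggerLexicon,
    terms: Sequence[PropositionTerm] | None = None,
    options: EngineOptions | None = None,
) -> FixtureCorpus:
    """Generate a seeded synthetic corpus of gold-labeled pairs.

    Fully deterministic for a fixed config. ``options`` defaults to the
    config's scope limit with the lexicon's profile; gold labels are
    derived with respect to exactly these options and this lexicon, and
    every non-ambiguous record is cross-checked against
    :func:`oracle_label` before being emitted.
    """
    if terms is None:
        terms = default_terms()
    if not terms:
        raise ValueError("terms must be non-empty")
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    if options is None:
        options = EngineOptions(scope_limit=config.scope_limit, profile=lexicon.profile)
    builder = _Builder(config, lexicon, terms, options)
    records = tuple(builder.build(i) for i in range(config.n_sentences))
    return FixtureCorpus(records=records, config=config, options=options)


def oracle_label(
    sentence: SentenceRecord,
    proposition_span: tuple[int, int],
    lexicon: TriggerLexicon,
    options: EngineOptions | None = None,
) -> str:
    """Brute-force re-statement of the scope rule, for property testing.

    Enumerates every phrase at every position with plain loops, selects
    leftmost-longest non-overlapping occurrences per category, applies
    pseudo masking, the refined ``utan`` rule, the window and the
    conjunction cut — sharing no code with :func:`negex_sv.engine.decide`.
    Returns ``"negated"`` or ``"not_negated"``.
    """
    options = options or EngineOptions()
    toks = [t.surface.casefold() for t in sentence.tokens]
    punct = [t.is_punct for t in sentence.tokens]
    ps, pe = proposition_span
    if not (0 <= ps < pe <= len(toks)):
        raise ValueError(f"proposition span {proposition_span} out of bounds")

    # all candidate matches, then greedy leftmost-longest per category
    chosen: dict[str, list[tuple[int, int, str]]] = {}
    for category in ("PREN", "POST", "PSEU", "CONJ"):
        candidates = []
        for phrase in lexicon.entries:
            if phrase.category.value != category:
                continue
            ptoks = [t.casefold() for t in phrase.tokens]
            for i in range(len(toks) - len(ptoks) + 1):
                ok = True
                for j, ptok in enumerate(ptoks):
                    if toks[i + j] != ptok:
                        ok = False
                        break
                if ok:
                    candidates.append((i, i + len(ptoks), phrase.text))
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
        picked: list[tuple[int, int, str]] = []
        for start, end, text in candidates:
            clash = False
            for pstart, pend, _ in picked:
                if start < pend and pstart < end:
                    clash = True
                    break
            if not clash:
                picked.append((start, end, text))
        chosen[category] = picked

    def masked(start: int, end: int, text: str) -> bool:
        for p_start, p_end, _ in chosen["PSEU"]:
            if start < p_end and p_start < end:
                return True
        if options.profile == "refined" and text == "utan":
            for i in range(start):
                if toks[i] == "inte":
                    return True
        return False

    def word_distance(lo: int, hi: int) -> int:
        count = 0
        for i in range(lo, hi):
            if options.count_punctuation or not punct[i]:
                count += 1
        return count + 1

    def conj_between(lo: int, hi: int) -> bool:
        for c_start, c_end, _ in chosen["CONJ"]:
            if lo <= c_start and c_end <= hi:
                return True
        return False

    best: tuple[int, int, int] | None = None
    for start, end, text in chosen["PREN"]:
        if end <= ps and not masked(start, end, text):
            d = word_distance(end, ps)
            if d <= options.scope_limit:
                if options.use_conjunction_cut and conj_between(end, ps):
                    continue
                key = (d, 0, start)
                if best is None or key < best:
                    best = key
    for start, end, text in chosen["POST"]:
        if start >= pe and not masked(start, end, text):
            d = word_distance(pe, start)
            if d <= options.scope_limit:
                if options.use_conjunction_cut and conj_between(pe, start):
                    continue
                key = (d, 1, start)
                if best is None or key < best:
                    best = key
    return "negated" if best is not None else "not_negated"
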