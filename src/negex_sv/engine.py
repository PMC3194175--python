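"""The trigger-scope negation detection engine.

Given a sentence and a proposition (a disease/symptom mention) in it, the
engine decides whether the proposition is negated:

1. tokenize the sentence (whitespace split; leading/trailing punctuation of
   each chunk becomes separate punctuation tokens);
2. locate trigger-phrase occurrences per category, case-insensitively, with
   longest-match-first, left-to-right, non-overlapping matching;
3. mask PREN/POST occurrences covered by a pseudo-negation, and — under the
   refined profile — mask ``utan`` when an ``inte`` occurs earlier in the
   sentence (in that position ``utan`` is the conjunction *but*, not the
   preposition *without*);
4. the proposition is negated when it lies within the scope window (one to
   six words by default) after an unmasked pre-negation trigger or before an
   unmasked post-negation trigger, with no scope-terminating conjunction in
   between. The nearest qualifying trigger decides; PREN wins ties.

Word distance counts the non-punctuation tokens strictly between trigger and
proposition plus one, so adjacency is distance 1; punctuation can be made to
count via :class:`EngineOptions`.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field, replace
from enum import Enum

from .lexicon import TriggerCategory, TriggerLexicon, TriggerPhrase

__all__ = [
    "Token",
    "SentenceRecord",
    "TriggerOccurrence",
    "Label",
    "Rationale",
    "NegationDecision",
    "EngineOptions",
    "PropositionNotFound",
    "tokenize",
    "find_triggers",
    "apply_utan_rule",
    "decide",
    "classify",
    "find_proposition_spans",
]

_PUNCT_CHARS = frozenset(string.punctuation) | frozenset("…–—‘’“”«»´`§")


class PropositionNotFound(ValueError):
    """Raised when a proposition cannot be located in its sentence."""


@dataclass(frozen=True)
class Token:
    """A surface token with its half-open character span in the raw text."""

    surface: str
    start: int
    end: int

    @property
    def is_punct(self) -> bool:
        return all(c in _PUNCT_CHARS for c in self.surface)


@dataclass(frozen=True)
class SentenceRecord:
    """A tokenized sentence; the unit of detection."""

    id: str
    text: str
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if not (0 <= tok.start < tok.end <= len(self.text)):
                raise ValueError(f"token span {tok} out of bounds for {self.text!r}")
            if tok.start < prev_end:
                raise ValueError("token spans must be non-overlapping and increasing")
            if self.text[tok.start : tok.end] != tok.surface:
                raise ValueError(f"token surface {tok.surface!r} does not match text span")
            prev_end = tok.end

    def surfaces(self, casefold: bool = False) -> tuple[str, ...]:
        if casefold:
            return tuple(t.surface.casefold() for t in self.tokens)
        return tuple(t.surface for t in self.tokens)


def tokenize(text: str, id: str = "s0") -> SentenceRecord:
    """Tokenize raw sentence text.

    Whitespace-separated chunks are split further so that each leading or
    trailing punctuation character becomes its own punctuation token;
    word-internal punctuation (hyphens, abbreviation dots) stays inside the
    token. Raises ``ValueError`` for empty/whitespace-only input.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")
    tokens: list[Token] = []
    for match in re.finditer(r"\S+", text):
        chunk, start = match.group(), match.start()
        left, right = 0, len(chunk)
        leading: list[Token] = []
        while left < right and chunk[left] in _PUNCT_CHARS:
            leading.append(Token(chunk[left], start + left, start + left + 1))
            left += 1
        trailing: list[Token] = []
        while right > left and chunk[right - 1] in _PUNCT_CHARS:
            trailing.append(Token(chunk[right - 1], start + right - 1, start + right))
            right -= 1
        tokens.extend(leading)
        if right > left:
            tokens.append(Token(chunk[left:right], start + left, start + right))
        tokens.extend(reversed(trailing))
    return SentenceRecord(id=id, text=text, tokens=tuple(tokens))


@dataclass(frozen=True)
class TriggerOccurrence:
    """A trigger phrase located at a half-open token span.

    ``masked`` occurrences are present for provenance but never negate;
    ``mask_reason`` is ``"pseudo"`` (covered by a pseudo-negation) or
    ``"utan_rule"`` (the refined-profile disambiguation).
    """

    phrase: TriggerPhrase
    start: int
    end: int
    masked: bool = False
    mask_reason: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("occurrence span must be non-empty")
        if self.end - self.start != self.phrase.n_tokens:
            raise ValueError("occurrence span length must equal the phrase token count")

    def overlaps(self, other: "TriggerOccurrence") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def category(self) -> TriggerCategory:
        return self.phrase.category


class Label(str, Enum):
    NEGATED = "negated"
    NOT_NEGATED = "not_negated"


class Rationale(str, Enum):
    PRE_TRIGGER_IN_SCOPE = "pre_trigger_in_scope"
    POST_TRIGGER_IN_SCOPE = "post_trigger_in_scope"
    NO_TRIGGER = "no_trigger"
    OUT_OF_SCOPE = "out_of_scope"
    PSEUDO_MASKED = "pseudo_masked"
    CONJUNCTION_CUT = "conjunction_cut"
    RULE_MASKED = "rule_masked"


@dataclass(frozen=True)
class NegationDecision:
    """The engine's verdict for one (sentence, proposition) pair."""

    label: Label
    proposition_span: tuple[int, int]
    rationale: Rationale
    trigger: TriggerOccurrence | None = None
    distance: int | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        negating = self.rationale in (
            Rationale.PRE_TRIGGER_IN_SCOPE,
            Rationale.POST_TRIGGER_IN_SCOPE,
        )
        if (self.label is Label.NEGATED) != (self.trigger is not None and negating):
            raise ValueError("negated decisions must carry an in-scope trigger, and only they")


@dataclass(frozen=True)
class EngineOptions:
    """Tunable engine behavior.

    ``scope_limit`` is the word window (default six); ``use_conjunction_cut``
    enables scope termination at conjunctions; ``profile`` selects the
    baseline or refined rule set (the refined profile activates the ``utan``
    disambiguation); ``count_punctuation`` makes punctuation tokens count
    toward the word window (historically unspecified; off by default).
    """

    scope_limit: int = 6
    use_conjunction_cut: bool = True
    profile: str = "baseline"
    count_punctuation: bool = False

    def __post_init__(self) -> None:
        if self.scope_limit < 1:
            raise ValueError("scope_limit must be >= 1")
        if self.profile not in ("baseline", "refined"):
            raise ValueError(f"unknown profile {self.profile!r}")


def find_triggers(sentence: SentenceRecord, lexicon: TriggerLexicon) -> list[TriggerOccurrence]:
    """Locate all trigger occurrences in a sentence.

    Matching is case-insensitive at token boundaries, longest-match-first,
    left-to-right and non-overlapping within each category (so ``inga
    tecken`` suppresses its sub-phrase ``inga``, while a pseudo-negation can
    still cover the PREN it contains). PREN/POST occurrences overlapping a
    PSEU occurrence come back masked; PSEU and CONJ occurrences are returned
    for provenance.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    surfaces = sentence.surfaces(casefold=True)
    occurrences: list[TriggerOccurrence] = []
    for category in TriggerCategory:
        phrases = lexicon.by_category(category)
        if not phrases:
            continue
        i = 0
        while i < len(surfaces):
            matched = None
            for phrase in phrases:  # longest-match-first by lexicon ordering
                n = phrase.n_tokens
                if surfaces[i : i + n] == tuple(t.casefold() for t in phrase.tokens):
                    matched = phrase
                    break
            if matched is not None:
                occurrences.append(TriggerOccurrence(matched, i, i + matched.n_tokens))
                i += matched.n_tokens
            else:
                i += 1

    pseudo = [o for o in occurrences if o.category is TriggerCategory.PSEU]
    masked: list[TriggerOccurrence] = []
    for occ in occurrences:
        if occ.category in (TriggerCategory.PREN, TriggerCategory.POST) and any(
            occ.overlaps(p) for p in pseudo
        ):
            occ = replace(occ, masked=True, mask_reason="pseudo")
        masked.append(occ)
    masked.sort(key=lambda o: (o.start, o.end, o.category.value))
    return masked


def apply_utan_rule(
    sentence: SentenceRecord, occurrences: list[TriggerOccurrence]
) -> list[TriggerOccurrence]:
    """Mask ``utan`` occurrences preceded by an earlier ``inte`` token.

    In that configuration ``utan`` is almost always the conjunction *but*
    (an *inte X utan Y* construction) rather than the negating preposition
    *without*. Part of the refined rule profile.
    """
    surfaces = sentence.surfaces(casefold=True)
    out: list[TriggerOccurrence] = []
    for occ in occurrences:
        if (
            occ.phrase.text == "utan"
            and not occ.masked
            and any(surfaces[i] == "inte" for i in range(occ.start))
        ):
            occ = replace(occ, masked=True, mask_reason="utan_rule")
        out.append(occ)
    return out


def _words_between(sentence: SentenceRecord, lo: int, hi: int, count_punctuation: bool) -> int:
    """Number of window-counting tokens with index in [lo, hi)."""
    if count_punctuation:
        return max(0, hi - lo)
    return sum(1 for i in range(lo, hi) if not sentence.tokens[i].is_punct)


def decide(
    sentence: SentenceRecord,
    proposition_span: tuple[int, int],
    occurrences: list[TriggerOccurrence],
    options: EngineOptions | None = None,
    pair_id: str | None = None,
) -> NegationDecision:
    """Apply the scope rule to one proposition given located triggers.

    The nearest unmasked in-scope trigger wins (PREN beats POST at equal
    distance, then the leftmost). When nothing qualifies, the most
    informative failure rationale is reported, in the order out-of-scope >
    conjunction-cut > pseudo/rule-masked > no trigger.
    """
    options = options or EngineOptions()
    prop_start, prop_end = proposition_span
    if not (0 <= prop_start < prop_end <= len(sentence.tokens)):
        raise ValueError(f"proposition span {proposition_span} out of bounds")

    conjunctions = [o for o in occurrences if o.category is TriggerCategory.CONJ]
    qualifying: list[tuple[int, int, int, TriggerOccurrence]] = []
    saw_out_of_scope = saw_cut = saw_pseudo = saw_rule = False

    for occ in occurrences:
        if occ.category is TriggerCategory.PREN and occ.end <= prop_start:
            gap_lo, gap_hi = occ.end, prop_start
            order = 0
        elif occ.category is TriggerCategory.POST and occ.start >= prop_end:
            gap_lo, gap_hi = prop_end, occ.start
            order = 1
        else:
            continue
        distance = _words_between(sentence, gap_lo, gap_hi, options.count_punctuation) + 1
        in_window = distance <= options.scope_limit
        if occ.masked:
            if in_window:
                if occ.mask_reason == "utan_rule":
                    saw_rule = True
                else:
                    saw_pseudo = True
            continue
        if not in_window:
            saw_out_of_scope = True
            continue
        if options.use_conjunction_cut and any(
            gap_lo <= c.start and c.end <= gap_hi for c in conjunctions
        ):
            saw_cut = True
            continue
        qualifying.append((distance, order, occ.start, occ))

    if qualifying:
        distance, order, _, occ = min(qualifying)
        rationale = (
            Rationale.PRE_TRIGGER_IN_SCOPE if order == 0 else Rationale.POST_TRIGGER_IN_SCOPE
        )
        return NegationDecision(
            Label.NEGATED, proposition_span, rationale, occ, distance, pair_id
        )
    if saw_out_of_scope:
        rationale = Rationale.OUT_OF_SCOPE
    elif saw_cut:
        rationale = Rationale.CONJUNCTION_CUT
    elif saw_pseudo:
        rationale = Rationale.PSEUDO_MASKED
    elif saw_rule:
        rationale = Rationale.RULE_MASKED
    else:
        rationale = Rationale.NO_TRIGGER
    return NegationDecision(Label.NOT_NEGATED, proposition_span, rationale, None, None, pair_id)


def find_proposition_spans(
    sentence: SentenceRecord, proposition_text: str, min_compound_len: int = 1
) -> list[tuple[int, int]]:
    """Token spans where a proposition occurs, exact first, then in-compound.

    An exact occurrence matches the proposition's token sequence
    case-insensitively; a compound occurrence is a single-token proposition
    of at least ``min_compound_len`` characters contained inside a longer
    token (Swedish compounds: ``astma`` in ``astmabesvär``).
    """
    prop_tokens = tuple(t.casefold() for t in proposition_text.split())
    if not prop_tokens:
        raise ValueError("proposition text must be non-empty")
    surfaces = sentence.surfaces(casefold=True)
    n = len(prop_tokens)
    spans = [
        (i, i + n) for i in range(len(surfaces) - n + 1) if surfaces[i : i + n] == prop_tokens
    ]
    if n == 1 and len(prop_tokens[0]) >= min_compound_len:
        needle = prop_tokens[0]
        for i, surface in enumerate(surfaces):
            if needle in surface and surface != needle and (i, i + 1) not in spans:
                spans.append((i, i + 1))
    return sorted(spans)


def classify(
    sentence_text: str,
    proposition_text: str,
    lexicon: TriggerLexicon,
    options: EngineOptions | None = None,
    sentence_id: str = "s0",
    pair_id: str | None = None,
) -> NegationDecision:
    """End-to-end detection for one (sentence, proposition) pair.

    Tokenizes, locates triggers, applies the refined-profile ``utan`` rule
    when active, and decides on the first proposition occurrence in token
    order (exact token match or compound containment). Deterministic for
    fixed inputs; raises :class:`PropositionNotFound` when the proposition
    does not occur in the sentence.
    """
    options = options or EngineOptions()
    sentence = tokenize(sentence_text, id=sentence_id)
    spans = find_proposition_spans(sentence, proposition_text)
    if not spans:
        raise PropositionNotFound(
            f"proposition {proposition_text!r} not found in sentence {sentence_text!r}"
        )
    occurrences = find_triggers(sentence, lexicon)
    if options.profile == "refined":
        occurrences = apply_utan_rule(sentence, occurrences)
    return decide(sentence, spans[0], occurrences, options, pair_id=pair_id)
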