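"""Proposition term lists and (sentence, proposition) pair construction.

Propositions — the diseases, symptoms and findings whose negation status is
decided — typically come from ICD-10-style code lists whose descriptions mix
the term itself with clarifiers ("Pneumoni, ej specificerad"). This module
cleans such raw descriptions, locates terms in sentences (including inside
Swedish compound tokens such as ``astmabesvär``), and builds the evaluation
pair list: one record per proposition occurrence per sentence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .engine import SentenceRecord, find_triggers
from .lexicon import TriggerCategory, TriggerLexicon

logger = logging.getLogger(__name__)

__all__ = [
    "PropositionTerm",
    "PropositionMatch",
    "SentencePropositionPair",
    "DEFAULT_CLARIFIERS",
    "clean_term",
    "read_term_file",
    "match_terms",
    "build_pairs",
    "split_by_trigger_presence",
]

#: Swedish clarifier phrases stripped from raw code-list descriptions.
DEFAULT_CLARIFIERS: tuple[str, ...] = (
    "ej specificerad",
    "ej specificerat",
    "ospecificerad",
    "ospecificerat",
    "ospecificerade",
    "andra specificerade former",
    "annan specificerad form",
    "utan närmare specifikation",
)

TERM_SOURCES = ("icd10", "ksh97p", "mesh", "user")


@dataclass(frozen=True)
class PropositionTerm:
    """A cleaned disease/symptom term, optionally with its source code."""

    surface: str
    source: str = "user"
    code: str | None = None

    def __post_init__(self) -> None:
        if not self.surface or self.surface != " ".join(self.surface.lower().split()):
            raise ValueError(
                f"term surface must be non-empty, lowercase and normalized: {self.surface!r}"
            )
        if self.source not in TERM_SOURCES:
            raise ValueError(f"unknown term source {self.source!r}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.surface.split())


@dataclass(frozen=True)
class PropositionMatch:
    """A term located in a sentence; ``compound`` when inside a longer token."""

    term: PropositionTerm
    start: int
    end: int
    compound: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("match span must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SentencePropositionPair:
    """One evaluation record: a sentence plus one proposition occurrence."""

    pair_id: str
    sentence: SentenceRecord
    match: PropositionMatch


def _strip_parentheses(raw: str) -> str:
    out: list[str] = []
    depth = 0
    for pos, char in enumerate(raw):
        if char == "(":
            depth += 1
        elif char == ")":
            if depth > 0:
                depth -= 1
            else:
                logger.warning("unbalanced ')' in term %r; dropping it", raw)
        elif depth == 0:
            out.append(char)
    if depth > 0:
        # everything from the unmatched '(' onward was already skipped
        logger.warning("unbalanced '(' in term %r; removed through end of string", raw)
    return "".join(out)


def clean_term(raw: str, clarifiers: Sequence[str] = DEFAULT_CLARIFIERS) -> str | None:
    """Normalize a raw code-list description into a matchable term.

    Removes parenthesized spans (nested included; an unbalanced opening
    parenthesis removes through the end of the string with a warning),
    strips the configured clarifier phrases together with adjacent commas,
    collapses whitespace and lowercases. Returns ``None`` when nothing
    remains. Idempotent.
    """
    text = _strip_parentheses(raw).lower()
    for clarifier in clarifiers:
        pattern = r"\s*,?\s*(?<!\w)" + re.escape(clarifier.lower()) + r"(?!\w)\s*,?\s*"
        text = re.sub(pattern, " ", text)
    text = " ".join(text.split()).strip(" ,").strip()
    return text or None


def read_term_file(
    path: str | Path,
    source: str = "user",
    clarifiers: Sequence[str] = DEFAULT_CLARIFIERS,
) -> list[PropositionTerm]:
    """Read a term list: one term per line, optionally ``code TAB description``.

    Descriptions are passed through :func:`clean_term`; lines whose residue
    is empty are skipped, duplicates keep the first occurrence.
    """
    path = Path(path)
    terms: list[PropositionTerm] = []
    seen: set[str] = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        code: str | None = None
        description = line
        if "\t" in line:
            code, _, description = line.partition("\t")
            code = code.strip() or None
        surface = clean_term(description, clarifiers)
        if surface is None or surface in seen:
            continue
        seen.add(surface)
        terms.append(PropositionTerm(surface, source=source, code=code))
    return terms


def match_terms(
    sentence: SentenceRecord,
    terms: Sequence[PropositionTerm],
    min_compound_len: int = 5,
) -> list[PropositionMatch]:
    """Locate every proposition term in a sentence.

    Exact token-sequence matches are always reported. A single-token term of
    at least ``min_compound_len`` characters additionally matches as a proper
    substring of a longer token (``compound=True``); the length floor guards
    against spurious hits from short terms inside unrelated compounds.
    Overlapping matches of different terms are all reported, sorted by span.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    if min_compound_len < 1:
        raise ValueError("min_compound_len must be >= 1")
    surfaces = sentence.surfaces(casefold=True)
    matches: list[PropositionMatch] = []
    for term in terms:
        ttoks = tuple(t.casefold() for t in term.tokens)
        n = len(ttoks)
        for i in range(len(surfaces) - n + 1):
            if surfaces[i : i + n] == ttoks:
                matches.append(PropositionMatch(term, i, i + n, compound=False))
        if n == 1 and len(ttoks[0]) >= min_compound_len:
            needle = ttoks[0]
            for i, surface in enumerate(surfaces):
                if needle in surface and surface != needle:
                    matches.append(PropositionMatch(term, i, i + 1, compound=True))
    matches.sort(key=lambda m: (m.start, m.end, m.term.surface))
    return matches


def build_pairs(
    sentences: Iterable[SentenceRecord],
    terms: Sequence[PropositionTerm],
    min_compound_len: int = 5,
) -> list[SentencePropositionPair]:
    """One evaluation record per (sentence, proposition occurrence).

    A sentence with several proposition occurrences contributes one record
    per occurrence; sentences without any are dropped. Output order is
    sentence order, then span order.
    """
    pairs: list[SentencePropositionPair] = []
    for sentence in sentences:
        for k, match in enumerate(match_terms(sentence, terms, min_compound_len)):
            pairs.append(SentencePropositionPair(f"{sentence.id}#{k}", sentence, match))
    return pairs


def split_by_trigger_presence(
    pairs: Sequence[SentencePropositionPair], lexicon: TriggerLexicon
) -> tuple[list[SentencePropositionPair], list[SentencePropositionPair]]:
    """Partition pairs into trigger-bearing and trigger-free groups.

    A pair is trigger-bearing when its sentence contains at least one
    PREN/POST/PSEU occurrence, masked or not; conjunctions alone do not
    count. The partition is exhaustive and disjoint.
    """
    relevant = {TriggerCategory.PREN, TriggerCategory.POST, TriggerCategory.PSEU}
    with_trigger: list[SentencePropositionPair] = []
    without_trigger: list[SentencePropositionPair] = []
    cache: dict[str, bool] = {}
    for pair in pairs:
        key = pair.sentence.id
        if key not in cache:
            occurrences = find_triggers(pair.sentence, lexicon)
            cache[key] = any(o.category in relevant for o in occurrences)
        (with_trigger if cache[key] else without_trigger).append(pair)
    return with_trigger, without_trigger
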