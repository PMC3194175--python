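"""Trigger lexicons for NegEx-style negation detection in Swedish clinical text.

A trigger lexicon is a set of cue phrases, each tagged with one of four
categories:

* ``PREN`` — pre-negation: negates a proposition that follows it
  (``inga tecken`` *no signs of*).
* ``POST`` — post-negation: negates a proposition that precedes it
  (``osannolik`` *unlikely*).
* ``PSEU`` — pseudo-negation: looks like a negation but must not trigger one
  (``inte säkert om`` *not certain if*).
* ``CONJ`` — scope-terminating conjunction: cuts a trigger's scope
  (``men`` *but*).

Lexicons are read and written in the classic NegEx triggers-file dialect:
one ``<phrase> TAB+ [TAG]`` entry per line, ``#`` comments, UTF-8,
case-insensitive matching. Two Swedish lexicons ship with the package:
``swedish_baseline`` and ``swedish_refined`` (the latter drops the
false-positive-prone trigger ``icke`` and is meant to be paired with the
engine's ``utan`` disambiguation rule).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TriggerCategory",
    "Origin",
    "TriggerPhrase",
    "TriggerLexicon",
    "TriggerFileError",
    "read_trigger_file",
    "write_trigger_file",
    "load_builtin_lexicon",
    "select_by_frequency",
    "BUILTIN_PROFILES",
]

BUILTIN_PROFILES = ("baseline", "refined")


class TriggerCategory(str, Enum):
    """The four trigger-phrase categories."""

    PREN = "PREN"
    POST = "POST"
    PSEU = "PSEU"
    CONJ = "CONJ"


class Origin(str, Enum):
    """Provenance of a lexicon entry (base entry vs. generated variant)."""

    BASE = "base"
    QUANTIFIER_FORM = "quantifier_form"
    ADJECTIVE_INFLECTION = "adjective_inflection"
    VERB_INFLECTION = "verb_inflection"
    WORD_ORDER_VARIANT = "word_order_variant"
    MANUAL = "manual"


class TriggerFileError(ValueError):
    """Raised for malformed or empty trigger files."""


@dataclass(frozen=True)
class TriggerPhrase:
    """One categorized trigger phrase.

    ``text`` is lowercased and single-space separated. Generated variants
    (``origin`` other than ``base``/``manual``) carry the phrase they were
    derived from in ``lemma``.
    """

    text: str
    category: TriggerCategory
    origin: Origin = Origin.BASE
    lemma: str | None = None

    def __post_init__(self) -> None:
        if not self.text or self.text != " ".join(self.text.split()):
            raise ValueError(
                f"trigger phrase text must be non-empty and whitespace-normalized: {self.text!r}"
            )
        if self.text != self.text.lower():
            raise ValueError(f"trigger phrase text must be lowercase: {self.text!r}")
        if self.origin in (Origin.BASE, Origin.MANUAL):
            if self.lemma is not None:
                raise ValueError("base/manual entries must not carry a lemma")
        elif self.lemma is None:
            raise ValueError(f"generated entry {self.text!r} must carry its source lemma")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.text.split())

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def key(self) -> tuple[str, TriggerCategory]:
        return (self.text, self.category)


class TriggerLexicon:
    """A set of :class:`TriggerPhrase` entries, unique by (text, category).

    Iteration yields entries in non-increasing token-length order
    (longest-match-first), with alphabetical text as the deterministic
    tie-break.
    """

    def __init__(
        self,
        entries: Iterable[TriggerPhrase] = (),
        profile: str = "baseline",
        on_duplicate: str = "warn",
    ) -> None:
        if profile not in BUILTIN_PROFILES:
            raise ValueError(f"unknown profile {profile!r}; expected one of {BUILTIN_PROFILES}")
        self.profile = profile
        self._entries: dict[tuple[str, TriggerCategory], TriggerPhrase] = {}
        for entry in entries:
            self.add(entry, on_duplicate=on_duplicate)

    def add(self, entry: TriggerPhrase, on_duplicate: str = "warn") -> None:
        """Add an entry; duplicate (text, category) keeps the first copy."""
        if entry.key in self._entries:
            if on_duplicate == "warn":
                logger.warning(
                    "duplicate trigger entry (%r, %s) collapsed", entry.text, entry.category.value
                )
            elif on_duplicate == "error":
                raise ValueError(f"duplicate trigger entry ({entry.text!r}, {entry.category.value})")
            return
        self._entries[entry.key] = entry

    def __iter__(self) -> Iterator[TriggerPhrase]:
        return iter(
            sorted(
                self._entries.values(),
                key=lambda p: (-p.n_tokens, p.text, p.category.value),
            )
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, TriggerPhrase):
            return item.key in self._entries
        if isinstance(item, tuple) and len(item) == 2:
            text, category = item
            return (text, TriggerCategory(category)) in self._entries
        return False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TriggerLexicon):
            return NotImplemented
        return set(self._entries) == set(other._entries)

    @property
    def entries(self) -> tuple[TriggerPhrase, ...]:
        return tuple(self)

    def by_category(self, category: TriggerCategory) -> tuple[TriggerPhrase, ...]:
        """Entries of one category, longest-match-first."""
        return tuple(p for p in self if p.category is category)

    def get(self, text: str, category: TriggerCategory) -> TriggerPhrase | None:
        return self._entries.get((text, category))

    def keys(self) -> set[tuple[str, TriggerCategory]]:
        return set(self._entries)


# one phrase, one or more tabs, a bracketed tag, optional trailing comment
_LINE_RE = re.compile(r"^(?P<phrase>[^\t]+)\t+\[(?P<tag>[A-Za-z]+)\]\s*(?:#.*)?$")


def read_trigger_file(path: str | Path, profile: str = "baseline") -> TriggerLexicon:
    """Parse a triggers file into a :class:`TriggerLexicon`.

    Each non-blank, non-comment line must be ``<phrase> TAB+ [TAG]`` with a
    known category tag. Phrases are lowercased and whitespace-normalized;
    duplicate (text, category) lines collapse to one entry with a warning.
    Raises :class:`TriggerFileError` on malformed lines or an empty file.
    """
    path = Path(path)
    lexicon = TriggerLexicon(profile=profile)
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            match = _LINE_RE.match(line)
            if match is None:
                raise TriggerFileError(f"{path}:{lineno}: malformed trigger line {line!r}")
            phrase = " ".join(match["phrase"].split()).lower()
            if not phrase:
                raise TriggerFileError(f"{path}:{lineno}: empty trigger phrase")
            tag = match["tag"].upper()
            try:
                category = TriggerCategory(tag)
            except ValueError:
                raise TriggerFileError(
                    f"{path}:{lineno}: unknown category tag [{tag}]"
                ) from None
            lexicon.add(TriggerPhrase(phrase, category))
    if len(lexicon) == 0:
        raise TriggerFileError(f"{path}: no trigger entries found")
    return lexicon


def write_trigger_file(lexicon: TriggerLexicon, path: str | Path) -> None:
    """Write a lexicon in the triggers-file dialect, sorted by (category, text).

    Round-trips losslessly on the (text, category) entry set. Raises
    ``ValueError`` for an empty lexicon.
    """
    if len(lexicon) == 0:
        raise ValueError("refusing to write an empty trigger lexicon")
    lines = [
        f"{entry.text}\t\t[{entry.category.value}]"
        for entry in sorted(lexicon, key=lambda p: (p.category.value, p.text))
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_builtin_lexicon(profile: str = "refined") -> TriggerLexicon:
    """Load a packaged Swedish lexicon (``baseline`` or ``refined``)."""
    if profile not in BUILTIN_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {BUILTIN_PROFILES}")
    ref = resources.files("negex_sv.data") / f"swedish_{profile}.txt"
    with resources.as_file(ref) as path:
        return read_trigger_file(path, profile=profile)


def select_by_frequency(
    candidates: TriggerLexicon, corpus: Sequence[str], k: int
) -> TriggerLexicon:
    """Keep the ``k`` most corpus-frequent PREN/POST candidates.

    Occurrences are counted case-insensitively at token boundaries over the
    tokenized corpus. Ties break toward the longer phrase, then
    alphabetically. PSEU and CONJ entries are always retained regardless of
    rank: they guard precision, not recall.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate entries")
    if not corpus:
        raise ValueError("corpus must be non-empty")

    from .engine import tokenize  # local import to avoid a module cycle

    token_lists = [
        [t.surface.casefold() for t in tokenize(text).tokens] for text in corpus if text.strip()
    ]

    def count(phrase: TriggerPhrase) -> int:
        ptoks = [t.casefold() for t in phrase.tokens]
        n = len(ptoks)
        total = 0
        for toks in token_lists:
            for i in range(len(toks) - n + 1):
                if toks[i : i + n] == ptoks:
                    total += 1
        return total

    ranked = sorted(
        (p for p in candidates if p.category in (TriggerCategory.PREN, TriggerCategory.POST)),
        key=lambda p: (-count(p), -p.n_tokens, p.text),
    )
    selected = ranked[: min(k, len(ranked))]
    guards = [
        p for p in candidates if p.category in (TriggerCategory.PSEU, TriggerCategory.CONJ)
    ]
    return TriggerLexicon(selected + guards, profile=candidates.profile)
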