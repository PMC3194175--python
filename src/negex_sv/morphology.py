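"""Swedish morphological expansion of trigger lexicons.

English trigger phrases map onto several Swedish surface forms: the negative
quantifier *no* has three gender/number forms (``ingen``/``inga``/``inget``),
adjectives and verbs inflect, and subordinate clauses invert the verb–adverb
order (*har inte* → *inte har*). This module generates those variants from a
base lexicon using explicit suffix-rule paradigms plus an override table for
irregular verbs, behind a pluggable-paradigm interface: anyone with a full
morphological analyzer can supply richer paradigms through the same types.

Only what trigger expansion needs is implemented; this is not a general
Swedish morphology.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lexicon import Origin, TriggerLexicon, TriggerPhrase

logger = logging.getLogger(__name__)

__all__ = [
    "InflectionParadigm",
    "ExpansionError",
    "expand_quantifier_no",
    "inflect",
    "word_order_variants",
    "expand_lexicon",
    "read_paradigm_file",
    "default_paradigms",
    "DEFAULT_POS_ANNOTATIONS",
    "DEFAULT_NEGATING_ADVERBS",
]

#: The common negating adverbs that participate in word-order inversion.
DEFAULT_NEGATING_ADVERBS = frozenset({"inte", "ej", "icke", "aldrig"})

#: Default part-of-speech annotations for tokens of the packaged phrases.
DEFAULT_POS_ANNOTATIONS: Mapping[str, str] = {
    "ha": "verb",
    "har": "verb",
    "hade": "verb",
    "haft": "verb",
    "visa": "verb",
    "visar": "verb",
    "visade": "verb",
    "visat": "verb",
    "förneka": "verb",
    "förnekar": "verb",
    "ingen": "quantifier",
    "inga": "quantifier",
    "inget": "quantifier",
    "osannolik": "adjective",
}

_ORIGIN_BY_POS = {
    "adjective": Origin.ADJECTIVE_INFLECTION,
    "verb": Origin.VERB_INFLECTION,
    "quantifier": Origin.QUANTIFIER_FORM,
}


class ExpansionError(ValueError):
    """Raised when a lexicon expansion exceeds its variant cap."""


@dataclass(frozen=True)
class InflectionParadigm:
    """An ordered suffix-rule table for one part of speech.

    ``rules`` is a list of ``(lemma-suffix pattern, replacement suffixes)``
    pairs; the first matching rule wins and an empty pattern is the
    catch-all that terminates every paradigm (appended automatically when
    missing). ``overrides`` holds irregular form groups: any member of a
    group inflects to the whole group.
    """

    pos: str
    rules: tuple[tuple[str, tuple[str, ...]], ...]
    overrides: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        rules = tuple((p, tuple(r)) for p, r in self.rules)
        if not rules or rules[-1][0] != "":
            rules = rules + (("", ()),)
        object.__setattr__(self, "rules", rules)
        object.__setattr__(self, "overrides", tuple(frozenset(g) for g in self.overrides))

    def override_group(self, form: str) -> frozenset[str] | None:
        for group in self.overrides:
            if form in group:
                return group
        return None


def _builtin_paradigms() -> dict[str, InflectionParadigm]:
    ref = resources.files("negex_sv.data") / "inflection_rules.txt"
    with resources.as_file(ref) as path:
        return read_paradigm_file(path)


def default_paradigms() -> dict[str, InflectionParadigm]:
    """The packaged adjective/verb/quantifier paradigms, keyed by pos."""
    return _builtin_paradigms()


def read_paradigm_file(path: str | Path) -> dict[str, InflectionParadigm]:
    """Parse a plain-text paradigm rules file.

    Format: ``[pos]`` section headers; rule lines
    ``suffix-pattern TAB repl1,repl2,...`` (empty pattern = catch-all);
    lines starting with ``=`` list an irregular override group.
    """
    path = Path(path)
    sections: dict[str, tuple[list, list]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            sections.setdefault(current, ([], []))
            continue
        if current is None:
            raise ValueError(f"{path}:{lineno}: rule line before any [pos] section header")
        rules, overrides = sections[current]
        if line.lstrip().startswith("="):
            forms = tuple(f.strip() for f in line.lstrip()[1:].split(",") if f.strip())
            if len(forms) < 2:
                raise ValueError(f"{path}:{lineno}: override group needs at least two forms")
            overrides.append(frozenset(forms))
            continue
        if "\t" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'pattern TAB replacements'")
        pattern, _, rhs = line.partition("\t")
        replacements = tuple(r.strip() for r in rhs.split(",") if r.strip())
        rules.append((pattern.strip(), replacements))
    return {
        pos: InflectionParadigm(pos=pos, rules=tuple(rules), overrides=tuple(overrides))
        for pos, (rules, overrides) in sections.items()
    }


def expand_quantifier_no() -> set[str]:
    """The three gender/number forms of the Swedish negative quantifier *no*."""
    return {"ingen", "inga", "inget"}


def inflect(lemma: str, paradigm: InflectionParadigm) -> set[str]:
    """All surface forms of ``lemma`` under ``paradigm`` (always includes it).

    Irregular override groups win over suffix rules; otherwise the first
    matching suffix rule is applied.
    """
    if not lemma or not lemma.strip():
        raise ValueError("lemma must be non-empty")
    lemma = lemma.strip().casefold()
    group = paradigm.override_group(lemma)
    if group is not None:
        return set(group) | {lemma}
    for pattern, replacements in paradigm.rules:
        if lemma.endswith(pattern):
            stem = lemma[: len(lemma) - len(pattern)] if pattern else lemma
            return {stem + r for r in replacements} | {lemma}
    return {lemma}  # unreachable: the catch-all always matches


def word_order_variants(
    phrase: str | Sequence[str],
    adverbs: Iterable[str] | None = None,
) -> set[str]:
    """Subordinate-clause word-order inversions of a trigger phrase.

    For every adjacent (verb, adverb) bigram whose adverb is one of the
    common negating adverbs, the phrase with that bigram swapped (adverb
    before verb) is emitted alongside the original. A single-token phrase
    has nothing to invert and is returned unchanged with a logged notice.
    """
    tokens = tuple(phrase.split()) if isinstance(phrase, str) else tuple(phrase)
    adverb_set = DEFAULT_NEGATING_ADVERBS if adverbs is None else frozenset(adverbs)
    if len(tokens) < 2:
        logger.info("word_order_variants: single-token phrase %r, nothing to invert", phrase)
        return {" ".join(tokens)}
    variants = {" ".join(tokens)}
    for i in range(len(tokens) - 1):
        first, second = tokens[i], tokens[i + 1]
        if second in adverb_set and first not in adverb_set:
            swapped = tokens[:i] + (second, first) + tokens[i + 2 :]
            variants.add(" ".join(swapped))
    return variants


def expand_lexicon(
    base: TriggerLexicon,
    paradigms: Mapping[str, InflectionParadigm] | None = None,
    pos_annotations: Mapping[str, str] | None = None,
    max_variants_per_entry: int = 64,
) -> TriggerLexicon:
    """Expand a base lexicon with inflections and word-order variants.

    Every base entry is retained. Tokens annotated adjective/verb/quantifier
    are inflected and the cross-product of token-level variants added; then
    word-order inversions are generated for every non-inverted entry that
    contains a negating adverb. Generated entries carry a non-base origin
    and their source phrase as ``lemma``. Pseudo-negations are expanded the
    same way as PREN/POST entries, so a pseudo form keeps masking all the
    inflected negation forms it subsumes. The operation is idempotent and
    only ever grows the entry set.
    """
    if len(base) == 0:
        raise ValueError("base lexicon must be non-empty")
    if paradigms is None:
        paradigms = default_paradigms()
    if pos_annotations is None:
        pos_annotations = DEFAULT_POS_ANNOTATIONS

    result = TriggerLexicon(base, profile=base.profile, on_duplicate="ignore")

    for entry in base:
        if entry.origin not in (Origin.BASE, Origin.MANUAL):
            continue  # generated forms regenerate from their base; skip re-inflection
        annotated = [pos_annotations.get(tok) for tok in entry.tokens]
        if not any(pos in _ORIGIN_BY_POS for pos in annotated):
            continue
        variant_lists: list[set[str]] = []
        for tok, pos in zip(entry.tokens, annotated):
            if pos in _ORIGIN_BY_POS and pos in paradigms:
                variant_lists.append(inflect(tok, paradigms[pos]))
            else:
                variant_lists.append({tok})
        n_variants = 1
        for variants in variant_lists:
            n_variants *= len(variants)
        if n_variants > max_variants_per_entry:
            raise ExpansionError(
                f"entry {entry.text!r} expands to {n_variants} variants "
                f"(cap {max_variants_per_entry})"
            )
        origin = next(_ORIGIN_BY_POS[pos] for pos in annotated if pos in _ORIGIN_BY_POS)
        for combo in itertools.product(*(sorted(v) for v in variant_lists)):
            text = " ".join(combo)
            if text == entry.text:
                continue
            result.add(
                TriggerPhrase(text, entry.category, origin=origin, lemma=entry.text),
                on_duplicate="ignore",
            )

    # word-order pass over everything produced so far (but never re-inverting
    # an inversion, which keeps the expansion a fixpoint)
    for entry in list(result):
        if entry.origin is Origin.WORD_ORDER_VARIANT:
            continue
        if not any(tok in DEFAULT_NEGATING_ADVERBS for tok in entry.tokens):
            continue
        for text in word_order_variants(entry.tokens):
            if text == entry.text:
                continue
            result.add(
                TriggerPhrase(
                    text, entry.category, origin=Origin.WORD_ORDER_VARIANT, lemma=entry.text
                ),
                on_duplicate="ignore",
            )
    return result
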