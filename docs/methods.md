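# Methods

## The detection model

`negex-sv` implements trigger-scope negation detection: a purely lexical,
regular-language model in which a proposition is negated exactly when it
falls inside the scope window of a live negation trigger. The model
assumes (a) sentence-level scope — negation never crosses a sentence
boundary; (b) that scope is well approximated by surface word distance
rather than syntax; and (c) that a fixed lexicon of cue phrases covers the
negation vocabulary of the genre. These assumptions are known to be
imperfect (conditional clauses, long-range scope, uncertainty hedges), and
the evaluation harness exists precisely to quantify the cost.

Decision procedure for one (sentence, proposition) pair:

1. **Tokenization.** Whitespace split; leading/trailing punctuation of each
   chunk becomes separate one-character punctuation tokens; word-internal
   hyphens and dots stay put. Character offsets are preserved so every
   token maps back into the raw text.
2. **Trigger matching.** Per category (PREN, POST, PSEU, CONJ), phrases are
   matched case-insensitively at token boundaries, longest-first,
   left-to-right, non-overlapping *within the category*. Categories are
   matched independently so that a pseudo-negation can cover the shorter
   negation it contains (*inte säkert om* over *inte*); any PREN/POST
   occurrence whose span overlaps a PSEU occurrence is masked. Overlap
   (not exact-span equality) is used because pseudo phrases typically
   contain the negation token they neutralize.
3. **Swedish disambiguation (refined profile).** *icke* is absent from the
   refined lexicon: in clinical Swedish it virtually always opens a disease
   name (*icke allergisk astma*), where the disease is present. An *utan*
   occurrence is masked when any earlier token in the sentence is *inte*:
   in the *inte X utan Y* construction *utan* is the conjunction *but*.
   The rule is evaluated at sentence granularity on purpose — no
   distance limit — because the construction it targets is itself
   unbounded.
4. **Scope decision.** For each unmasked PREN occurrence ending before the
   proposition (symmetrically POST after it), the distance is the number
   of non-punctuation tokens strictly between trigger and proposition,
   plus one; adjacency is distance 1. The proposition is negated when some
   trigger has distance ≤ `scope_limit` and, if the conjunction cut is
   active, no CONJ occurrence lies strictly between. The nearest
   qualifying trigger decides; PREN beats POST at equal distance, then the
   leftmost. Failures are reported with the most informative rationale:
   out-of-scope > conjunction-cut > pseudo/rule-masked > no trigger.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `scope_limit` | 6 words | classic 1–6 word window |
| `use_conjunction_cut` | true | terminate scope at CONJ phrases |
| `profile` | `baseline` (library) / `refined` (CLI) | rule set; refined = no *icke*, *utan* rule on |
| `count_punctuation` | false | punctuation tokens count toward the window |
| `min_compound_len` | 5 chars | shortest single-token term matched inside compounds |

Whether the original formulation counted punctuation, or the trigger's own
tokens, toward the window was never specified; this implementation takes
the strictest reading consistent with the canonical worked example
(adjacent trigger ⇒ distance 1) and exposes punctuation counting as an
option. Nearest-trigger-wins with PREN precedence is likewise a design
choice where the literature is silent — it is the least surprising rule
and is exactly what the independent oracle implements.

## The packaged lexicons

Two trigger files ship in `negex_sv/data/`: `swedish_baseline.txt` and
`swedish_refined.txt` (identical minus *icke*). The PREN section is the
set of Swedish phrases printed in the published frequency and
manual-annotation tables for this approach; no Swedish POST/PSEU/CONJ
phrases were ever printed, so those sections are this package's own
Swedish renderings of the canonical English examples (*unlikely*, *not
certain if*, the conjunction *but* and close relatives) and are documented
as reconstructions. The full original evaluation list (41 triggers) was
only ever distributed at a now-external URL; users with their own list can
load it with `read_trigger_file` and cap it with `select_by_frequency`,
which ranks PREN/POST entries by corpus frequency while always retaining
PSEU/CONJ guards (they protect precision, not recall).

## Morphology

Instead of an external inflection service, expansion uses explicit
suffix-rule paradigms (first matching rule wins; an empty-pattern
catch-all terminates every paradigm) plus an override table for irregular
verbs (*ha/har/hade/haft*, *se/ser/såg/sett*, …), all replaceable through
`read_paradigm_file`. The adjective paradigm produces the -t/-a concord
forms with two orthographic guards (doubled final consonant collapses
before -t; a lemma already ending in -t adds only -a); the verb paradigm
covers the first conjugation; the quantifier paradigm is the
*ingen/inga/inget* group. Word-order inversion applies only to phrases
containing one of the four common negating adverbs (*inte, ej, icke,
aldrig*). `expand_lexicon` is idempotent (generated entries are never
re-inflected or re-inverted, and regenerate identically from their base),
never deletes a base entry, and refuses cross-products above 64 variants
per entry — a guard against pathological paradigms, not a linguistic
claim.

## The synthetic corpus

`fixtures.generate` emulates the two-group evaluation design so the
package is fully testable without restricted clinical data. Each record is
a template: filler tokens around an optional trigger and a proposition at
a sampled word distance, with optional compound embedding, a
pseudo-negation, a scope-cutting conjunction, a benign (wrong-side)
trigger, an out-of-window trigger, an *icke* disease-name or *inte … utan*
contrast construction, or an uncertainty/conditional/past-condition
phrasing that makes the record *ambiguous*.

Defaults are fixed to the published study's regime: 900 pairs, overall
gold-negated rate 0.31 (the original corpus had 281/900), pseudo rate
0.05, ambiguous rate 0.12 (40% of ambiguous records carry an in-window
trigger — the class that becomes false positives after collapsing),
compound rate 0.15, and a distance distribution concentrated near the
trigger with 10% of mass beyond the six-word window. The simulated second
rater flips the collapsed class of 12.5% of trigger-group records,
preferring *ambiguous* as the flip target (72%); at ~0.48 trigger-group
prevalence this reproduces the published agreement regime (≈87%
agreement, κ ≈ 0.75). These rates were fixed from the study design before
any measurement and are not tuned.

**What the generator does and does not show.** Gold labels are *derivable
by construction*: a record is gold-negated iff an unmasked trigger lies
within the window, with respect to the lexicon and options passed to
`generate` — every non-ambiguous record is verified against the
brute-force oracle at generation time. Consequently recall on fixture
corpora is 1.0 by construction, and all realistic error mass enters
through the ambiguous class and through profile mismatch (evaluating a
refined-generated corpus under the baseline profile reintroduces the
*icke*/*utan* false positives). Passing tests therefore demonstrate that
the implementation realizes the scope model exactly, and how the
refinement changes precision — not field performance on real clinical
text, whose annotation noise, spelling variation and syntax the templates
deliberately do not model.

`fixtures.oracle_label` is an independent re-statement of the whole
decision procedure in plain loops (naive phrase scanning,
greedy leftmost-longest selection, explicit masking/window/cut checks),
sharing no code with `engine.decide`; the acceptance suite requires 100%
agreement between the two on ≥10,000 generated pairs spanning both
profiles, all categories, distances 1–8 and compound propositions.

## Statistics

Metrics use *negated* as the positive class; ambiguous gold collapses into
*not negated* before scoring. Confidence intervals are Wald,
p ± z·√(p(1−p)/n) with z = Φ⁻¹(0.975), clipped to [0, 1], with each
metric's own denominator as n. Wald was chosen because it reproduces the
intervals conventionally reported with this design to within ~0.1–0.2
percentage points; the published intervals themselves were computed by an
unstated method, so exact agreement is not claimed and the CI machinery is
pluggable (`ci_method`). A metric with a zero denominator is reported as
undefined rather than raising. Cohen's κ uses the standard
marginal-product chance correction and is undefined (returns `None`) for
a shared constant label. The two-proportion comparison is the plain
Pearson χ² on the 2×2 table, 1 df, no continuity correction — the default
reading of "the χ² test" — and degenerate tables (pooled proportion 0
or 1) return (0, 1). Per-trigger statistics attribute each negated
decision to exactly one deciding trigger (the engine's nearest winner), so
the table's occurrence counts are mutually exclusive.

## Numerical and degenerate-input choices

* Tokenizer, matcher and distances are pure integer arithmetic; the only
  floating-point code is in the statistics, where closed forms are used
  and `scipy.stats` supplies the normal quantile and χ² tail.
* Ties in trigger matching break alphabetically after length; ties in the
  per-trigger table break by occurrences then phrase; both make every
  output deterministic.
* Duplicate lexicon lines collapse with a warning; an empty trigger file,
  an empty lemma, an empty term residue, a zero-length sentence and an
  out-of-bounds proposition span are all errors at the boundary rather
  than silent degradation.
* All generator randomness flows through one `random.Random(seed)`;
  identical configs are byte-identical across runs.

## Problem sizes

The default test suite and the acceptance script generate all data at run
time: corpora of 900–1,000 records for pipeline checks and 3×3,400
records for the oracle-equivalence sweep, sizes at which every quantity
the package reports is stable to well under a percentage point across
seeds while the whole suite completes in well under a minute.

## Known limitations

* No detection of historical/hypothetical conditions or experiencers, no
  uncertainty classification, no cross-sentence negation — all outside
  the scope model.
* Compound matching is substring containment with a length floor, not
  morphological decompounding; short terms inside unrelated compounds are
  the known failure mode the floor mitigates.
* The packaged POST/PSEU/CONJ entries are reconstructions (see above);
  the packaged part-of-speech annotations cover the packaged phrases
  only.
* The suffix-rule inflector is intentionally minimal; supply a paradigm
  file or a full analyzer through the same interface for broader
  coverage.
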