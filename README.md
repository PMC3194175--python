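# negex-sv

Rule-based negation detection for Swedish clinical text.

When a physician writes *"inga tecken på pneumoni"* (*no signs of
pneumonia*), the disease mention must not be indexed as present: clinical
notes reason largely by excluding diagnoses, so negation detection is a
prerequisite for any text mining over patient records. `negex-sv` is a
Swedish adaptation of the classic trigger-phrase approach to this problem,
built for clinical NLP researchers and engineers who need a transparent,
fully rule-based baseline plus the evaluation machinery to score it.

## The algorithm

Given a sentence and a *proposition* (a disease/symptom mention, located
even inside compound tokens such as *astmabesvär*), the engine:

1. matches a categorized trigger lexicon against the tokenized sentence —
   pre-negations (PREN, e.g. *inga tecken*), post-negations (POST, e.g.
   *osannolik*), pseudo-negations (PSEU, e.g. *inte säkert om*) and
   scope-terminating conjunctions (CONJ, e.g. *men*) — case-insensitively,
   longest match first;
2. masks PREN/POST occurrences covered by a pseudo-negation, and, under the
   *refined* profile, masks *utan* whenever *inte* occurs earlier in the
   sentence (there *utan* is the conjunction *but*, not *without*);
3. declares the proposition **negated** iff an unmasked PREN trigger
   precedes it (or POST trigger follows it) within a scope window of
   1–6 words, with no conjunction in between. The nearest qualifying
   trigger decides; distance 1 means adjacency and punctuation does not
   count toward the window.

Swedish needs a larger trigger lexicon than English: the quantifier *no*
has three gender/number forms (*ingen/inga/inget*), adjectives and verbs
inflect, and subordinate clauses invert verb–adverb order (*har inte* →
*inte har*). The `morphology` module generates these variants from base
entries via suffix-rule paradigms and an irregular-verb override table.

The evaluation harness mirrors the standard two-group design: three-class
gold annotations (affirmed/negated/ambiguous) collapsed to two classes,
precision/recall/specificity/NPV with 95% Wald intervals on the
trigger-bearing group, NPV on the trigger-free group, per-trigger frequency
and precision tables, two-rater percent agreement and Cohen's κ, and a
Pearson χ² comparison of two proportions.

## Worked example

```python
from negex_sv import EngineOptions, classify, load_builtin_lexicon

lexicon = load_builtin_lexicon("refined")
options = EngineOptions(profile="refined")

for text in ("Pat har inga tecken på pneumoni",
             "icke allergisk astma",
             "han är inte pigg utan astmabesvär"):
    proposition = "pneumoni" if "pneumoni" in text else "astma"
    d = classify(text, proposition, lexicon, options)
    print(f"{text!r:45} -> {d.label.value:12}"
          f" trigger={d.trigger.phrase.text if d.trigger else '-'}"
          f" rationale={d.rationale.value}")
```

prints

```
'Pat har inga tecken på pneumoni'             -> negated      trigger=inga tecken rationale=pre_trigger_in_scope
'icke allergisk astma'                        -> not_negated  trigger=- rationale=no_trigger
'han är inte pigg utan astmabesvär'           -> negated      trigger=inte rationale=pre_trigger_in_scope
```

The first sentence is negated by the pre-negation *inga tecken* two words
from the proposition. The second is **not** negated under the refined
profile: *icke* opens a disease name (*non-atopic asthma*) and is excluded
from the refined lexicon (under `profile="baseline"` it would be a false
positive). In the third, the refined *utan* rule masks *utan* (here the
conjunction *but*), but the proposition is still within the window of the
live trigger *inte*, so it remains negated — the rule only removes *utan*
itself as a deciding trigger.

The same engine is exposed as a CLI (`negex-sv detect|extract|clean-terms|
evaluate|agreement|expand-lexicon|select-triggers|simulate`); all commands
read and write UTF-8 TSV and accept a YAML config file for defaults.

Because clinical corpora are access-restricted, the package ships a seeded
synthetic-corpus generator (`negex_sv.fixtures`) whose gold labels are
derivable by construction and verified against an independent brute-force
oracle; all tests run from generated data alone.

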