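# lexiclean

Rewrite and suppression rules for UMLS-style biomedical lexicons, with a
minimal dictionary-based concept recognizer to measure their impact on a
corpus.

## The problem

Dictionary-based biomedical term identification maps text spans to
thesaurus concepts (CUIs) via their attached term strings (SUIs).  Large
merged thesauri such as the UMLS Metathesaurus were not built for text
mining: they miss common surface variants ("Failure, Renal" is listed but
"Renal Failure" may not be), and they contain coding artifacts that are
poison for a matcher — synonyms like "2" or "EC 2.7.1.-", rubric terms
like "Other and unspecified leukaemia", template syntax like
"ADHESIVE @@ BANDAGE".  `lexiclean` curates a concept-term table for
matching by

* **nine rewrite rules** that add missing synonyms: syntactic inversion
  of `"A, B"` terms, possessive `'s` removal, Schwartz–Hearst-style
  short-form/long-form pairing of trailing parenthesized abbreviations,
  removal of angular-bracket metadata, of trailing semantic-type
  parentheticals, and of parenthesized/bracketed groups at the beginning
  or end of a term; and
* **eight suppression rules** that remove undesired terms: terms reduced
  to single characters or numbers after tokenization and stop-word
  removal, dosage expressions, `@`-containing terms, enzyme
  classification numbers, NEC/NOS classification and underspecification
  rubrics, residual categories ("Other …"), and terms longer than five
  words.

Every generated term passes a duplicate/homonym guard: a new term is not
added if its normal form (lowercase, punctuation stripped) already exists
under the same concept (duplicate) or any other concept (homonym —
logged, never matched).  The parenthetical rules and the words>5 rule do
not apply to concepts in the *Chemicals & Drugs* semantic group, whose
names legitimately carry brackets and length.

The shipped **recommended profile** enables rewrite rules 1–5 and
suppression rules S1–S7 — the subset whose output survives manual review;
the **full profile** enables all seventeen.

A deliberately minimal recognizer (case-insensitive, punctuation-ignoring
token-sequence lookup, largest match OFF so nested terms count for both
the longer and the shorter term) and counting utilities quantify, per
rule, the occurrences / distinct terms / distinct concepts gained by
rewriting and lost by suppression in a one-document-per-line corpus.

Real UMLS releases are licensed, so the package includes a first-class
synthetic fixture generator: seeded lexicons whose terms provably trigger
exactly one rule each, engineered guard collisions, Chemicals &
Drugs-typed twins, and corpora with planted term occurrences padded by a
disjoint nonsense vocabulary, making every expected count exact.

## Worked example

```python
from lexiclean import RuleConfig, apply_rules
from lexiclean.fixtures import golden_fixture

fx = golden_fixture()   # the frozen worked-example lexicon
result = apply_rules(fx.lexicon(), fx.semmap, RuleConfig.from_profile("recommended"))
print(result.report.to_tsv())
print(f"{result.n_input} terms in, {len(result.lexicon)} out")
```

prints

```
rule_id	rule	added	suppressed	homonyms	homonym_pct
1	syntactic_inversion	3	0	0	0.0
2	possessives	2	0	0	0.0
3	short_long_form	3	0	0	0.0
4	angular_brackets	2	0	0	0.0
5	semantic_type	2	0	0	0.0
S1	short_token	0	2	0	0.0
S2	dosages	0	2	0	0.0
S3	at_sign	0	1	0	0.0
S4	ec_numbers	0	2	0	0.0
S5	any_classification	0	2	0	0.0
S6	any_underspecification	0	2	0	0.0
S7	miscellaneous	0	2	0	0.0

49 terms in, 48 out
```

Twelve synonyms were generated (e.g. `R1-1 ← "Renal Failure"` from
"Failure, Renal", `R3-2 ← "SSRIs"` from "Selective Serotonin Reuptake
Inhibitors (SSRIs)", `R5-2 ← "Heart"` from "Heart (Body Part, Organ, or
Organ Component)") and thirteen undesired terms were suppressed (e.g.
"10*9/L", "Oxygen 2%", "EC 2.7.1.-", "Injury, NEC"), so the 49 input
terms become 48 output terms (49 + 12 − 13).  Generated rows carry
reserved `R<rule>-<n>` string ids for traceability; re-running the same
profile on the output adds and suppresses nothing.

The same pipeline is available from the shell:

```sh
lexiclean apply concepts.rrf semtypes.rrf out.rrf --dialect reduced \
    --profile recommended --report report.tsv
lexiclean delta concepts.rrf semtypes.rrf --rule S3 --dialect reduced
lexiclean annotate out.rrf corpus.txt --dialect reduced
lexiclean profiles
```

## Layout

| module | contents |
| --- | --- |
| `lexiclean.normalization` | shared normal form, tokenizer, stop words, numeral predicates |
| `lexiclean.lexicon_io` | RRF-dialect concept/semantic-type tables, filtering, dedup, `Lexicon` |
| `lexiclean.rewrite_rules` | the nine synonym-generating rules |
| `lexiclean.suppression_rules` | the eight suppression predicates |
| `lexiclean.engine` | configuration/profiles, guard, pipeline, audit report |
| `lexiclean.recognizer` | term index, annotation, corpus statistics, before/after deltas |
| `lexiclean.fixtures` | synthetic fixture generator and the golden worked-example set |
| `lexiclean.cli` | `lexiclean apply / delta / annotate / profiles` |

See `docs/methods.md` for the precise rule semantics and design choices.
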