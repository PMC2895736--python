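# Methods

This note records the exact semantics of the curation rules, the design
choices made where the rule statements leave room, and what the synthetic
fixtures do and do not establish.

## One normal form

Deduplication, the duplicate/homonym guard, and the corpus matcher all
compare strings through a single normal form: lowercase, every
punctuation character replaced by a space, whitespace runs collapsed.
Punctuation is the Unicode punctuation categories plus the symbols
`* / @ + = < >`; letters and digits are never punctuation.  Replacement
by space (rather than deletion) is forced by the tokenization behaviour
the short-token rule depends on: `10*9/L` must become the three tokens
`10 9 l`, not the single token `109l`.  Hyphens are punctuation, so
`insulin-like` normalizes to `insulin like`; the raw-text word counter
used by the words>5 rule splits on whitespace only, so the same string
still counts as one word there.

Sharing one normal form is a correctness property, not a convenience: a
candidate the guard admits is exactly a string the matcher can find, and
a string judged a within-concept duplicate can never be matched as a
separate term.

## Input handling

Concept-term tables are pipe-delimited in the 18-field MRCONSO layout or
a declared 5-field reduced layout (`concept_id|language|string_id|
suppress|text|`); the dialect is configuration, never sniffed.  The
default extraction filter keeps English, non-NLM-suppressible strings of
at most 255 characters.  Within each concept the first record per
normal-form key (in input order) is kept; which duplicate survives is
otherwise arbitrary, and first-wins was chosen for determinism.  Source
preference flags (TS/STT/ISPREF) are preserved but not consulted.
Identical strings under *different* concepts are homonyms, not
duplicates, and are all kept.  Original rows round-trip byte-for-byte;
generated rows receive `R<rule>-<counter>` string ids.  Files are UTF-8.

## Rewrite rules

1. **Syntactic inversion** — `"A, B"` → `"B A"`, only when exactly one
   comma-space pattern is present and no token (trailing punctuation
   stripped, case-insensitive) is in the preposition/conjunction list
   `{of in on for to by with at from and or nor but as versus vs}`
   (vendored, replaceable).  The join is a single space.
2. **Possessives** — every word-final `'s` (ASCII or U+2019 apostrophe,
   before whitespace or end of string) is removed.  Plural possessives
   (`s'`) and attached forms (`Alzheimer's-type`) are out of scope.
3. **Short form / long form** — the term is treated as a definition
   context `LONG FORM (SF)`.  The candidate short form is the
   parenthesized group at the very end; it must be 2–10 characters, at
   most two words, contain a letter, and start alphanumerically.  The
   long form is found by right-to-left character matching in a window of
   `min(|SF|+5, 2·|SF|)` words before the parenthesis, with the short
   form's first character anchored at a word start.  Two dictionary-
   specific conditions apply on top: terminal position, and equal first
   letters of both forms (case-insensitive).  On success *both* forms
   become candidates.  The pairing can be wrong in characteristic ways —
   `"Polibar Rapid (P/P)"` does yield `P/P` — which is faithful,
   documented behaviour; the engine flags this rule's output for review.
4. **Angular brackets** — all non-nested `<…>` spans are removed in one
   pass, whitespace re-collapsed.  Also review-flagged (template terms
   such as `every <integer> weeks` rewrite to the meaningless
   `every weeks`).
5. **Semantic type** — a trailing `(X)` is removed when `X`
   case-insensitively equals a semantic-type name from the vendored
   type-name list (a mid-2000s Semantic Network snapshot, 134 names,
   replaceable).  Parentheses only; a bracketed `[Finding]` variant was
   considered and rejected as unattested.
6.–9. **Begin/end parentheses/brackets** — a balanced delimiter group at
   the term's start (end) is removed with adjacent whitespace.  Balance
   is tracked by depth scanning, not regex, so `t(3;6)(p13;q25)` strips
   only `(p13;q25)`.  Unbalanced delimiters yield no candidate (never an
   error).  None of the four applies to Chemicals & Drugs concepts; the
   exclusion is stated once and applies to all four.

No rule emits its own input, an empty string, or cascades onto generated
terms (cascading syntactic inversion would oscillate).

## Suppression rules

* **S1 short token** — tokenize, drop stop words (vendored 133-word
  historical PubMed list); suppress when nothing remains or every
  remaining token is a single character, an arabic number (digits with
  at most one decimal point), or a well-formed roman numeral (1–3999,
  subtractive notation).  An empty remainder counts as suppressible —
  the motivating case is a concept whose only term is the stop word
  `WHILE`.
* **S2 dosages** — a number immediately (or after one space) followed by
  a percent/gram/microgram/milliliter unit token.  `mg` is deliberately
  absent from the default unit list (the rule targets those four unit
  families); the list is configuration-extensible.  Digits glued to a
  preceding letter (`B12`) never start a match.
* **S3 at-sign** — any `@`.
* **S4 EC numbers** — `EC` (case-sensitive, at a word boundary) plus 2–4
  dot-separated fields of digits or `-`.  Bare `2.7.1.112` without the
  prefix does not fire; all attested cases carry the prefix.
* **S5 / S6 classification & underspecification** — case-insensitive
  substrings (`not elsewhere classified`, `unclassified`, `without
  mention`; `not otherwise specified`, `not specified`, `unspecified`)
  anywhere, plus positional uppercase codes: `NEC`/`NOS` at the end
  preceded by a comma, or as `(NEC)`/`[NEC]` etc. at the end with a
  space before the opening delimiter.  The codes stay case-sensitive
  because they are coding conventions; `NECROSIS` and `DIAGNOSIS` must
  survive.
* **S7 miscellaneous** — `other` leading (with following space) or
  trailing (with preceding space); `deprecated unknown obsolete
  miscellaneous no` leading with following space; and whole-term
  equality with the keywords except `no` (the printed motivating example
  is the bare term `Other`; bare `NO` is instead left to S1's
  single-token path, which avoids suppressing the chemical symbol
  reading).  The "followed by a space" condition is applied to all five
  leading keywords; the alternative reading (only `no`) is grammatically
  possible but less consistent.
* **S8 words > 5** — more than five raw whitespace words; not applied to
  Chemicals & Drugs.  This rule is excluded from the recommended profile:
  it overwhelmingly removes legitimate long names.

All predicates are pure functions of the term text (plus word lists and
the group flag); verdicts carry the matched trigger for the audit trail.

## Pipeline order and idempotence

`apply_rules` runs: default filters → within-concept dedup → rewrite
rules in id order over all original terms → suppression rules in id
order over originals and surviving generated terms.  Each candidate
passes the guard (duplicate / homonym / empty) and is then vetted
against the enabled suppression rules *before* being added: a candidate
a suppression rule would remove (e.g. the generated `P/P`, all single
characters) is recorded as `skipped_suppressed` and never enters the
lexicon.  Without the vetting step such a candidate would be added and
suppressed afresh on every re-run; with it, re-running a profile on its
own output changes nothing, and the conservation identity
`|output| = |deduplicated input| + added − suppressed` holds with
`suppressed` counting only records actually removed.  Homonym-colliding
candidates are logged (count and percentage per rule in the report) but
never written to the output lexicon; a sidecar can expose them for
inspection.  Suppressed rows go to a sidecar in the input dialect plus a
trailing rule-id field.

`single_rule_delta` evaluates one rule in isolation — the same
evaluation discipline as per-rule impact measurement.

## Recognizer

The matcher is token-sequence exact over the shared normal form:
an index key matches at a position iff the document's token subsequence
equals it.  Largest match is off — every key occurring anywhere is
reported, including keys nested inside longer matches — because the
point is to observe the effect of curation, not to disambiguate.  The
implementation enumerates token n-grams up to the longest indexed key;
its contract is equality with a brute-force every-key-at-every-position
scan, enforced by test on randomized fixtures.  Occurrence counts are
per (string, concept) pairing; per-string totals are kept alongside so
the once-per-string reading remains available.  Documents are lines of
UTF-8 text with 1-based ids.

## Synthetic fixtures

The generator emulates the *structure* of the inputs — concept-term
tables, concept→semantic-type assignments, corpora with known term
occurrences — not their content or statistics.  Trigger terms are built
from templates that provably fire exactly one rule (cross-firing is
designed away: e.g. the trailing-parenthesis term's inner word starts
with a letter different from the candidate long form's first letter, so
the short/long-form rule cannot also fire); words are globally unique
nonsense syllable compounds screened against stop words, prepositions,
and numeral forms.  Corpus filler comes from a closed `zq`-prefixed
alphabet disjoint from every lexicon key, and planting refuses any term
whose key contains another indexed key as a proper contiguous
subsequence — together these make planted counts exactly what the
recognizer must report.  Chemicals & Drugs twins (same text, with and
without the group tag) exercise the exclusions; engineered same-concept
and cross-concept collisions exercise the guard.

Passing on these fixtures therefore demonstrates rule and bookkeeping
correctness, not linguistic realism: no statistical properties of
biomedical abstracts, no morphology, no ambiguity beyond the engineered
homonyms.  Scale conclusions (how many terms a rule would generate on a
full thesaurus and corpus) are out of scope by construction.  Default
problem sizes — tens of terms per fixture, a few hundred corpus tokens,
100 seeds for the matcher-oracle comparison — keep the whole suite and
the acceptance script in the seconds range while exercising every code
path.

## Known limitations

* The vendored stop-word and semantic-type lists are declared snapshots
  of the historical resources, not certified copies; both are
  configuration-replaceable.
* Rule 5 matches parenthesized type names only; rule 2 handles `'s`
  only; S4 requires the `EC` prefix.  Each is a documented reading of an
  ambiguous statement (see the per-rule notes above).
* The recognizer performs no disambiguation and no largest-match mode;
  both are deliberate non-goals.
* Whether corpus occurrence counts should be per string or per
  (string, concept) is genuinely ambiguous; both tallies are reported.
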