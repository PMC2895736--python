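"""Minimal dictionary-based concept recognizer and corpus counting.

The matcher is deliberately simple: case-insensitive, punctuation-ignoring
lookup of lexicon terms in text, with largest match turned OFF — nested
terms are reported both as a match for the longer and for the shorter
term.  Matching is token-sequence exact on the shared normal form, never
character-substring: "nose" can never match inside "diagnosed".

Documents are UTF-8 plain text, one document per line; document ids are
1-based line numbers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .engine import SUPPRESSED, PipelineResult, RuleEvent
from .lexicon_io import Lexicon, TermRecord
from .normalization import tokenize

__all__ = [
    "TermIndex",
    "MatchEvent",
    "CorpusStats",
    "build_index",
    "annotate",
    "corpus_stats",
    "before_after_delta",
    "read_corpus",
]


class TermIndex:
    """Mapping from normalized token sequences to the records holding them."""

    def __init__(self):
        self._entries: dict[tuple[str, ...], set[tuple[str, str]]] = {}
        self.max_len: int = 0
        self.skipped: list[str] = []  # string_ids whose key normalized to ""

    def add(self, rec: TermRecord) -> None:
        key = tuple(tokenize(rec.text).texts())
        if not key:
            self.skipped.append(rec.string_id)
            return
        self._entries.setdefault(key, set()).add((rec.concept_id, rec.string_id))
        self.max_len = max(self.max_len, len(key))

    def lookup(self, key: tuple[str, ...]) -> frozenset[tuple[str, str]]:
        return frozenset(self._entries.get(key, ()))

    def __contains__(self, key: tuple[str, ...]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def keys(self) -> Iterator[tuple[str, ...]]:
        return iter(self._entries)


def build_index(lexicon: Iterable[TermRecord]) -> TermIndex:
    """Index the normalized token sequences of all lexicon records.

    Records whose key is empty (pure punctuation) are skipped and logged
    on ``index.skipped``.
    """
    index = TermIndex()
    for rec in lexicon:
        index.add(rec)
    return index


@dataclass(frozen=True)
class MatchEvent:
    """One recognized term occurrence: a token span in one document."""

    doc_id: int
    start: int  # token offsets, half-open
    end: int
    key: tuple[str, ...]
    records: frozenset[tuple[str, str]]  # (concept_id, string_id)

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("match span must cover at least one token")


def annotate(document: str, index: TermIndex, doc_id: int = 1) -> list[MatchEvent]:
    """Report EVERY index key occurring as a contiguous token subsequence.

    Includes keys nested inside longer matches and overlapping matches;
    events are ordered by (start, end).
    """
    toks = tokenize(document).texts()
    n = len(toks)
    events: list[MatchEvent] = []
    for start in range(n):
        limit = min(index.max_len, n - start)
        for length in range(1, limit + 1):
            key = tuple(toks[start : start + length])
            recs = index.lookup(key)
            if recs:
                events.append(MatchEvent(doc_id, start, start + length, key, recs))
    return events


@dataclass
class CorpusStats:
    """Occurrence/term/concept tallies over a corpus.

    ``occurrences`` counts every match-event × record pairing once (a key
    shared by several concepts contributes one occurrence per concept);
    ``per_string`` additionally gives per-string totals so the
    once-per-string reading of the counts stays recoverable.
    """

    occurrences: int = 0
    string_ids: set[str] = field(default_factory=set)
    concept_ids: set[str] = field(default_factory=set)
    per_string: Counter = field(default_factory=Counter)
    per_record: Counter = field(default_factory=Counter)

    @property
    def distinct_terms(self) -> int:
        return len(self.string_ids)

    @property
    def distinct_concepts(self) -> int:
        return len(self.concept_ids)

    def update(self, events: Iterable[MatchEvent]) -> None:
        for ev in events:
            for cid, sid in ev.records:
                self.occurrences += 1
                self.string_ids.add(sid)
                self.concept_ids.add(cid)
                self.per_record[(cid, sid)] += 1
            self.per_string[ev.key] += 1

    def as_row(self) -> tuple[int, int, int]:
        return (self.occurrences, self.distinct_terms, self.distinct_concepts)


def corpus_stats(documents: Iterable[str], index: TermIndex) -> CorpusStats:
    """Aggregate :func:`annotate` over all documents."""
    stats = CorpusStats()
    for doc_id, doc in enumerate(documents, start=1):
        stats.update(annotate(doc, index, doc_id))
    return stats


def read_corpus(path: str | Path) -> list[str]:
    """Load a one-document-per-line UTF-8 corpus file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh]


@dataclass
class DeltaReport:
    """Per-rule before/after impact of rewriting and suppression."""

    rewrite: dict[int | str, CorpusStats]
    suppression: dict[int | str, CorpusStats]


def before_after_delta(
    corpus: Sequence[str],
    lexicon_before: Lexicon,
    lexicon_after: Lexicon,
    events: Sequence[RuleEvent],
) -> DeltaReport:
    """Impact of each rule on what is identified in the corpus.

    For every rewrite rule, counts the corpus occurrences / distinct terms
    / distinct concepts attributable to the terms that rule generated (and
    that survived into *lexicon_after*); for every suppression rule, the
    same three numbers for the terms it removed from *lexicon_before*.
    """
    if not events:
        raise ValueError("event log required to attribute deltas to rules")

    generated_by_rule: dict[int | str, list[TermRecord]] = {}
    suppressed_by_rule: dict[int | str, list[TermRecord]] = {}
    # Generated records are recovered from the after-lexicon's provenance
    # fields; suppressed ones from the event log (they are gone from it).
    for rec in lexicon_after:
        if rec.provenance == "generated":
            generated_by_rule.setdefault(int(rec.rule_id), []).append(rec)
    suppressed_sids = {
        ev.source_string_id: ev.rule_id for ev in events if ev.action == SUPPRESSED
    }
    for rec in lexicon_before:
        rule = suppressed_sids.get(rec.string_id)
        if rule is not None:
            suppressed_by_rule.setdefault(rule, []).append(rec)

    def _stats_for(records: list[TermRecord]) -> CorpusStats:
        idx = build_index(records)
        return corpus_stats(corpus, idx)

    return DeltaReport(
        rewrite={rid: _stats_for(recs) for rid, recs in sorted(generated_by_rule.items(), key=str)},
        suppression={rid: _stats_for(recs) for rid, recs in sorted(suppressed_by_rule.items(), key=str)},
    )


def delta_from_result(corpus: Sequence[str], before: Lexicon, result: PipelineResult) -> DeltaReport:
    """Convenience wrapper over :func:`before_after_delta`."""
    return before_after_delta(corpus, before, result.lexicon, result.events)
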