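"""Reading, filtering, deduplicating and writing concept-term tables.

The on-disk formats are the pipe-delimited RRF dialects used by the UMLS
Metathesaurus release files: a full 18-field MRCONSO-style dialect and a
reduced 5-field dialect (``concept_id|language|string_id|suppress|text|``)
convenient for hand-authored fixtures.  The dialect is always declared by
the caller, never sniffed.

Original rows are preserved byte-for-byte and round-trip unchanged through
read → write.  Rows generated by rewrite rules receive synthetic string
identifiers with a reserved ``R<rule>-<counter>`` prefix so they remain
traceable to the rule that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .normalization import normalize_key

__all__ = [
    "Dialect",
    "MRCONSO",
    "REDUCED",
    "TermRecord",
    "SemanticTypeMap",
    "Lexicon",
    "LexiconFormatError",
    "read_concept_table",
    "filter_default",
    "deduplicate_within_concept",
    "read_semantic_types",
    "write_concept_table",
]

UNGROUPED = "ungrouped"

#: Maximum term length retained by the default filter.
MAX_TERM_LENGTH = 255


class LexiconFormatError(ValueError):
    """Malformed row in a pipe-delimited input file."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class Dialect:
    """Field layout of a pipe-delimited concept-term table.

    ``n_fields`` counts the data fields; every row additionally ends with a
    trailing pipe, as in the RRF release files.
    """

    name: str
    n_fields: int
    concept_id: int
    language: int
    string_id: int
    suppress: int
    text: int
    source_vocab: int | None = None
    term_type: int | None = None


MRCONSO = Dialect(
    name="mrconso",
    n_fields=18,
    concept_id=0,
    language=1,
    string_id=5,
    suppress=16,
    text=14,
    source_vocab=11,
    term_type=12,
)

REDUCED = Dialect(
    name="reduced",
    n_fields=5,
    concept_id=0,
    language=1,
    string_id=2,
    suppress=3,
    text=4,
)

DIALECTS = {d.name: d for d in (MRCONSO, REDUCED)}


@dataclass(frozen=True)
class TermRecord:
    """One term string attached to a concept, with source metadata.

    ``provenance`` is ``"original"`` for rows read from an input table and
    ``"generated"`` for rows added by a rewrite rule, in which case
    ``rule_id`` names the generating rule.
    """

    concept_id: str
    string_id: str
    text: str
    language: str = "ENG"
    source_vocab: str = ""
    term_type: str = ""
    nlm_suppressible: bool = False
    provenance: str = "original"
    rule_id: str | None = None
    raw: str | None = None  # original line (no newline) for byte round-trip

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError(f"empty term text for string_id={self.string_id!r}")
        if self.provenance == "generated" and self.rule_id is None:
            raise ValueError("generated records must carry a rule id")

    @property
    def key(self) -> str:
        return normalize_key(self.text)


def _split_row(line: str, dialect: Dialect, path, lineno: int) -> list[str]:
    fields = line.split("|")
    # Trailing pipe => last element empty; tolerate its absence.
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) != dialect.n_fields:
        raise LexiconFormatError(
            path, lineno,
            f"expected {dialect.n_fields} fields ({dialect.name} dialect), got {len(fields)}",
        )
    return fields


def _record_from_fields(fields: list[str], dialect: Dialect, raw: str) -> TermRecord:
    return TermRecord(
        concept_id=fields[dialect.concept_id],
        string_id=fields[dialect.string_id],
        text=fields[dialect.text],
        language=fields[dialect.language],
        source_vocab=fields[dialect.source_vocab] if dialect.source_vocab is not None else "",
        term_type=fields[dialect.term_type] if dialect.term_type is not None else "",
        nlm_suppressible=fields[dialect.suppress] not in ("", "N"),
        raw=raw,
    )


def read_concept_table(path: str | Path, dialect: Dialect | str = MRCONSO) -> Iterator[TermRecord]:
    """Yield one :class:`TermRecord` per row of a concept-term table.

    Row order is preserved and the raw line is retained on each record.
    An empty file yields an empty stream; a row with the wrong field count
    raises :class:`LexiconFormatError` naming the line.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\r\n")
            if raw == "":
                continue
            fields = _split_row(raw, dialect, path, lineno)
            yield _record_from_fields(fields, dialect, raw)


def filter_default(records: Iterable[TermRecord]) -> Iterator[TermRecord]:
    """Default extraction filter: English, not NLM-suppressible, ≤255 chars."""
    for rec in records:
        if rec.nlm_suppressible:
            continue
        if rec.language != "ENG":
            continue
        if len(rec.text) > MAX_TERM_LENGTH:
            continue
        yield rec


class Lexicon:
    """Ordered collection of term records with a normalized-key index.

    The index maps each normalized key to the set of ``(concept_id,
    string_id)`` pairs holding it; it backs the duplicate/homonym guard and
    the recognizer.  Within one concept no two records may share a key.
    """

    def __init__(self):
        self._records: list[TermRecord] = []
        self._by_key: dict[str, set[tuple[str, str]]] = {}
        self._by_sid: dict[str, TermRecord] = {}

    # -- construction -------------------------------------------------

    def add(self, rec: TermRecord) -> None:
        """Add a record, enforcing index invariants.

        Raises ``ValueError`` on a reused string_id or on a same-concept
        normalized-key duplicate (callers guard first).
        """
        if rec.string_id in self._by_sid:
            raise ValueError(f"duplicate string_id {rec.string_id!r}")
        key = rec.key
        holders = self._by_key.get(key)
        if holders and any(cid == rec.concept_id for cid, _ in holders):
            raise ValueError(
                f"concept {rec.concept_id} already holds a term with key {key!r}"
            )
        self._records.append(rec)
        self._by_key.setdefault(key, set()).add((rec.concept_id, rec.string_id))
        self._by_sid[rec.string_id] = rec

    def remove(self, string_id: str) -> TermRecord:
        rec = self._by_sid.pop(string_id)
        self._records.remove(rec)
        holders = self._by_key[rec.key]
        holders.discard((rec.concept_id, rec.string_id))
        if not holders:
            del self._by_key[rec.key]
        return rec

    # -- queries ------------------------------------------------------

    def holders(self, key: str) -> frozenset[tuple[str, str]]:
        """All (concept_id, string_id) pairs whose record has this key."""
        return frozenset(self._by_key.get(key, ()))

    def concepts_for_key(self, key: str) -> frozenset[str]:
        return frozenset(cid for cid, _ in self._by_key.get(key, ()))

    def __contains__(self, string_id: str) -> bool:
        return string_id in self._by_sid

    def __getitem__(self, string_id: str) -> TermRecord:
        return self._by_sid[string_id]

    def __iter__(self) -> Iterator[TermRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[TermRecord]:
        return list(self._records)

    def concept_ids(self) -> frozenset[str]:
        return frozenset(r.concept_id for r in self._records)


def deduplicate_within_concept(records: Iterable[TermRecord]) -> Lexicon:
    """Build a :class:`Lexicon`, keeping the first record per (concept, key).

    Cross-concept duplicates (homonyms) are both kept; only duplicates
    within the same concept are dropped.  First-in-input-order wins.
    """
    lex = Lexicon()
    seen: set[tuple[str, str]] = set()
    for rec in records:
        pair = (rec.concept_id, rec.key)
        if pair in seen:
            continue
        seen.add(pair)
        lex.add(rec)
    return lex


@dataclass
class SemanticTypeMap:
    """Concept → semantic types → semantic groups.

    A concept belongs to a group if ANY of its semantic types maps to that
    group; types absent from the group map resolve to ``"ungrouped"``.
    """

    concept_types: dict[str, frozenset[str]] = field(default_factory=dict)
    type_groups: dict[str, str] = field(default_factory=dict)  # lowercased type name -> group

    def types_of(self, concept_id: str) -> frozenset[str]:
        return self.concept_types.get(concept_id, frozenset())

    def group_of_type(self, type_name: str) -> str:
        return self.type_groups.get(type_name.lower(), UNGROUPED)

    def groups_of(self, concept_id: str) -> frozenset[str]:
        return frozenset(self.group_of_type(t) for t in self.types_of(concept_id))

    def in_group(self, concept_id: str, group: str) -> bool:
        return group in self.groups_of(concept_id)


def read_semantic_types(
    concept_type_path: str | Path,
    group_map_path: str | Path,
) -> SemanticTypeMap:
    """Read an MRSTY-dialect concept-type table and a SemGroups-dialect map.

    MRSTY rows: ``concept_id|type_id|tree_number|type_name|…`` (at least 4
    fields).  SemGroups rows: ``group_abbrev|group_name|type_id|type_name``.
    """
    concept_types: dict[str, set[str]] = {}
    path = Path(concept_type_path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\r\n")
            if raw == "":
                continue
            fields = raw.split("|")
            if fields and fields[-1] == "":
                fields = fields[:-1]
            if len(fields) < 4:
                raise LexiconFormatError(path, lineno, "expected at least 4 fields (MRSTY dialect)")
            concept_types.setdefault(fields[0], set()).add(fields[3])

    type_groups: dict[str, str] = {}
    path = Path(group_map_path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\r\n")
            if raw == "" or raw.startswith("#"):
                continue
            fields = raw.split("|")
            if fields and fields[-1] == "":
                fields = fields[:-1]
            if len(fields) != 4:
                raise LexiconFormatError(path, lineno, "expected 4 fields (SemGroups dialect)")
            _, group_name, _, type_name = fields
            type_groups[type_name.lower()] = group_name

    return SemanticTypeMap(
        concept_types={c: frozenset(ts) for c, ts in concept_types.items()},
        type_groups=type_groups,
    )


def _format_row(rec: TermRecord, dialect: Dialect, extra: str | None = None) -> str:
    fields = [""] * dialect.n_fields
    fields[dialect.concept_id] = rec.concept_id
    fields[dialect.language] = rec.language
    fields[dialect.string_id] = rec.string_id
    fields[dialect.suppress] = "N" if not rec.nlm_suppressible else "Y"
    fields[dialect.text] = rec.text
    if dialect.source_vocab is not None:
        fields[dialect.source_vocab] = rec.source_vocab
    if dialect.term_type is not None:
        fields[dialect.term_type] = rec.term_type
    row = "|".join(fields) + "|"
    if extra is not None:
        row += extra + "|"
    return row


def format_record(rec: TermRecord, dialect: Dialect, extra: str | None = None) -> str:
    """Serialize one record in *dialect*.

    Original records with a retained raw line round-trip byte-identically
    (unless an *extra* trailing field, e.g. a suppressing rule id, is
    requested).
    """
    if rec.raw is not None and extra is None:
        return rec.raw
    if rec.raw is not None:
        return rec.raw + extra + "|"
    return _format_row(rec, dialect, extra)


def write_concept_table(
    lexicon: Iterable[TermRecord],
    path: str | Path,
    dialect: Dialect | str = MRCONSO,
) -> None:
    """Write records to *path* in *dialect*.

    Untouched original rows are emitted byte-for-byte as read; generated
    rows are serialized from their fields (their string_ids carry the
    reserved ``R<rule>-<n>`` prefix assigned by the rule engine).
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for rec in lexicon:
            fh.write(format_record(rec, dialect) + "\n")


def write_suppressed_sidecar(
    suppressed: Iterable[tuple[TermRecord, str]],
    path: str | Path,
    dialect: Dialect | str = MRCONSO,
) -> None:
    """Write suppressed rows to a sidecar: input dialect + appended rule id."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for rec, rule_id in suppressed:
            fh.write(format_record(rec, dialect, extra=rule_id) + "\n")
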