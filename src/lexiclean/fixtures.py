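"""Deterministic synthetic fixtures: lexicons, semantic types, corpora.

Real UMLS releases and MEDLINE are licensed and enormous; every other
module in this package is therefore exercised on synthetic fixtures built
here.  Two kinds are provided:

* a seeded random fixture (:func:`generate_lexicon`,
  :func:`generate_corpus`): per-rule trigger terms built from templates
  that provably fire exactly one rule, plus distractors, engineered
  duplicate/homonym collisions, and Chemicals & Drugs-typed twins to
  exercise the exclusions.  Corpus documents embed chosen terms (surface
  varied within normalization equivalence) at recorded positions, padded
  with filler drawn from a closed "zq"-prefixed nonsense alphabet that is
  verifiably disjoint from every lexicon key, so planted counts are exact.

* a frozen golden fixture (:func:`golden_fixture` and the
  ``GOLDEN_*_CASES`` tables): the canonical worked examples for each rule
  ("Failure, Renal", "Chondria <beetle>", "10*9/L", …), including the
  known-incorrect outputs that the rules do generate by design
  ("Polibar Rapid (P/P)", "[pyruvate dehydrogenase (lipoamide)]
  phosphatase activity").

Same seed + spec ⇒ byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .lexicon_io import (
    Lexicon,
    REDUCED,
    SemanticTypeMap,
    TermRecord,
    deduplicate_within_concept,
    write_concept_table,
)
from .normalization import is_arabic_number, is_roman_numeral, tokenize
from .recognizer import build_index
from .resources import load_prepositions, load_stopwords

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "Fixture",
    "CorpusFixture",
    "generate_lexicon",
    "generate_corpus",
    "golden_fixture",
    "GOLDEN_REWRITE_CASES",
    "GOLDEN_NO_REWRITE_CASES",
    "GOLDEN_SUPPRESSION_CASES",
    "GOLDEN_KEPT_CASES",
]

ALL_RULE_IDS: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9,
                       "S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")

CHEM_TYPE = "Pharmacologic Substance"
PLAIN_TYPE = "Finding"


@dataclass
class FixtureSpec:
    """Knobs of the random fixture; all counts ≥ 0, defaults small."""

    seed: int = 0
    trigger_counts: Mapping = None  # rule id -> count; default 1 each
    distractors: int = 5
    homonym_collisions: int = 1
    duplicate_collisions: int = 1
    chem_exclusion_pairs: int = 1  # per chem-excluded rule (6-9, S8)
    n_documents: int = 4
    occurrences_per_term: int = 2

    def __post_init__(self):
        if self.trigger_counts is None:
            self.trigger_counts = {rid: 1 for rid in ALL_RULE_IDS}
        for v in list(self.trigger_counts.values()) + [
            self.distractors, self.homonym_collisions, self.duplicate_collisions,
            self.chem_exclusion_pairs, self.n_documents, self.occurrences_per_term,
        ]:
            if v < 0:
                raise ValueError("fixture counts must be non-negative")


@dataclass
class GroundTruth:
    """Expected rule firings and planted corpus spans, by construction."""

    rewrites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    suppressions: dict[str, str] = field(default_factory=dict)
    guard: list[tuple[str, int, str, str]] = field(default_factory=list)
    chem_pairs: list[tuple] = field(default_factory=list)  # (rule, chem_sid, plain_sid)
    planted_counts: dict[str, int] = field(default_factory=dict)
    planted_spans: list[tuple[int, int, int, str]] = field(default_factory=list)


@dataclass
class Fixture:
    spec: FixtureSpec | None
    records: list[TermRecord]
    semmap: SemanticTypeMap
    truth: GroundTruth

    def lexicon(self) -> Lexicon:
        return deduplicate_within_concept(self.records)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write concept table (reduced dialect), semantic-type table and
        ground-truth TSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "concepts": outdir / "concepts.rrf",
            "types": outdir / "semtypes.rrf",
            "truth": outdir / "groundtruth.tsv",
        }
        write_concept_table(self.records, paths["concepts"], REDUCED)
        with paths["types"].open("w", encoding="utf-8") as fh:
            for cid in sorted(self.semmap.concept_types):
                for t in sorted(self.semmap.concept_types[cid]):
                    fh.write(f"{cid}||{''}|{t}|\n")
        with paths["truth"].open("w", encoding="utf-8") as fh:
            fh.write("kind\tstring_id\trule_id\tdetail\n")
            for sid, items in sorted(self.truth.rewrites.items()):
                for rid, text in items:
                    fh.write(f"rewrite\t{sid}\t{rid}\t{text}\n")
            for sid, rid in sorted(self.truth.suppressions.items()):
                fh.write(f"suppress\t{sid}\t{rid}\t\n")
            for sid, rid, text, action in self.truth.guard:
                fh.write(f"guard\t{sid}\t{rid}\t{action}:{text}\n")
        return paths


_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "hi", "ja", "ke", "lu", "mi",
    "pa", "re", "so", "tu", "ve", "wo", "xi", "yo", "zu",
)


class _WordPool:
    """Globally unique nonsense words, safe against accidental rule firing."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()
        self._avoid = load_stopwords() | load_prepositions()

    def word(self) -> str:
        while True:
            n = self.rng.randint(2, 3)
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n))
            if w in self.used or w in self._avoid:
                continue
            if is_roman_numeral(w) or is_arabic_number(w):
                continue
            self.used.add(w)
            return w

    def reserve(self, w: str) -> bool:
        """Claim an arbitrary string (e.g. generated initials) if free."""
        lw = w.lower()
        if lw in self.used or lw in self._avoid or is_roman_numeral(lw):
            return False
        self.used.add(lw)
        return True


def _plain(word_pool: _WordPool, n: int, cap: bool = True) -> list[str]:
    ws = [word_pool.word() for _ in range(n)]
    return [w.capitalize() for w in ws] if cap else ws


def generate_lexicon(spec: FixtureSpec) -> Fixture:
    """Build the synthetic lexicon with per-rule trigger terms.

    Each enabled category yields terms that — by template construction —
    trigger exactly that one rule; Chemicals & Drugs-typed twins are added
    for the excluded rules, plus engineered duplicate and cross-concept
    homonym collisions for the guard, plus distractors triggering nothing.
    """
    rng = random.Random(spec.seed)
    pool = _WordPool(rng)
    truth = GroundTruth()
    records: list[TermRecord] = []
    concept_types: dict[str, set[str]] = {}

    counters = {"c": 0, "s": 0}

    def new_cid(chem: bool = False) -> str:
        counters["c"] += 1
        cid = f"C{counters['c']:04d}"
        concept_types[cid] = {CHEM_TYPE if chem else PLAIN_TYPE}
        return cid

    def add_term(text: str, cid: str | None = None, chem: bool = False) -> str:
        counters["s"] += 1
        sid = f"S{counters['s']:05d}"
        records.append(TermRecord(concept_id=cid or new_cid(chem), string_id=sid, text=text))
        return sid

    def expect_rewrite(sid: str, rule: int, text: str, action: str = "added") -> None:
        truth.rewrites.setdefault(sid, []).append((rule, text))
        truth.guard.append((sid, rule, text, action))

    # --- one block per rewrite-rule trigger category -------------------
    for _ in range(spec.trigger_counts.get(1, 0)):
        a, b = _plain(pool, 2)
        sid = add_term(f"{a}, {b}")
        expect_rewrite(sid, 1, f"{b} {a}")
    for _ in range(spec.trigger_counts.get(2, 0)):
        a, b = _plain(pool, 2)
        sid = add_term(f"{a}'s {b}")
        expect_rewrite(sid, 2, f"{a} {b}")
    for _ in range(spec.trigger_counts.get(3, 0)):
        while True:
            a, b = _plain(pool, 2)
            sf = (a[0] + b[0]).upper()
            if pool.reserve(sf):
                break
        sid = add_term(f"{a} {b} ({sf})", chem=True)  # chem blocks rules 6-9
        expect_rewrite(sid, 3, f"{a} {b}")
        expect_rewrite(sid, 3, sf)
    for _ in range(spec.trigger_counts.get(4, 0)):
        a, b, c = _plain(pool, 3)
        sid = add_term(f"{a} {b} <{c}>")
        expect_rewrite(sid, 4, f"{a} {b}")
    for _ in range(spec.trigger_counts.get(5, 0)):
        a, b = _plain(pool, 2)
        sid = add_term(f"{a} {b} ({PLAIN_TYPE})", chem=True)
        expect_rewrite(sid, 5, f"{a} {b}")
    for _ in range(spec.trigger_counts.get(6, 0)):
        a, b, c = _plain(pool, 3)
        sid = add_term(f"({a}) {b} {c}")
        expect_rewrite(sid, 6, f"{b} {c}")
    for _ in range(spec.trigger_counts.get(7, 0)):
        a, b, c = _plain(pool, 3)
        sid = add_term(f"[{a}] {b} {c}")
        expect_rewrite(sid, 7, f"{b} {c}")
    for _ in range(spec.trigger_counts.get(8, 0)):
        while True:
            a, b, c = _plain(pool, 3)
            if c[0].lower() not in (a[0].lower(), b[0].lower()):
                break  # keeps the short/long-form rule from also firing
        sid = add_term(f"{a} {b} ({c})")
        expect_rewrite(sid, 8, f"{a} {b}")
    for _ in range(spec.trigger_counts.get(9, 0)):
        a, b, c = _plain(pool, 3)
        sid = add_term(f"{a} {b} [{c}]")
        expect_rewrite(sid, 9, f"{a} {b}")

    # --- suppression-rule trigger categories ---------------------------
    for _ in range(spec.trigger_counts.get("S1", 0)):
        n1, n2 = rng.randint(10, 99), rng.randint(2, 9)
        ch = rng.choice("kqwz")
        sid = add_term(f"{n1}*{n2}/{ch}")
        truth.suppressions[sid] = "S1"
    for _ in range(spec.trigger_counts.get("S2", 0)):
        (a,) = _plain(pool, 1)
        n = rng.randint(2, 99)
        unit = rng.choice(("%", "gram", "ml", "mcg"))
        text = f"{a} {n}%" if unit == "%" else f"{a} {n} {unit}"
        truth.suppressions[add_term(text)] = "S2"
    for _ in range(spec.trigger_counts.get("S3", 0)):
        a, b = _plain(pool, 2)
        truth.suppressions[add_term(f"{a} @@ {b}")] = "S3"
    for _ in range(spec.trigger_counts.get("S4", 0)):
        (a,) = _plain(pool, 1)
        i, j, k = (rng.randint(1, 9) for _ in range(3))
        last = rng.choice([str(rng.randint(1, 200)), "-"])
        truth.suppressions[add_term(f"{a} EC {i}.{j}.{k}.{last}")] = "S4"
    for _ in range(spec.trigger_counts.get("S5", 0)):
        (a,) = _plain(pool, 1)
        truth.suppressions[add_term(f"{a} unclassified")] = "S5"
    for _ in range(spec.trigger_counts.get("S6", 0)):
        (a,) = _plain(pool, 1)
        truth.suppressions[add_term(f"{a} unspecified")] = "S6"
    for _ in range(spec.trigger_counts.get("S7", 0)):
        (a,) = _plain(pool, 1)
        truth.suppressions[add_term(f"Other {a}")] = "S7"
    for _ in range(spec.trigger_counts.get("S8", 0)):
        ws = _plain(pool, 6)
        truth.suppressions[add_term(" ".join(ws))] = "S8"

    # --- Chemicals & Drugs exclusion twins: same text, with and without
    # the group tag; the rule must fire only on the untagged twin. -------
    for rule in (6, 7, 8, 9, "S8"):
        for _ in range(spec.chem_exclusion_pairs):
            if rule == 6:
                a, b, c = _plain(pool, 3)
                text, gen = f"({a}) {b} {c}", f"{b} {c}"
            elif rule == 7:
                a, b, c = _plain(pool, 3)
                text, gen = f"[{a}] {b} {c}", f"{b} {c}"
            elif rule == 8:
                while True:
                    a, b, c = _plain(pool, 3)
                    if c[0].lower() not in (a[0].lower(), b[0].lower()):
                        break
                text, gen = f"{a} {b} ({c})", f"{a} {b}"
            elif rule == 9:
                a, b, c = _plain(pool, 3)
                text, gen = f"{a} {b} [{c}]", f"{a} {b}"
            else:  # S8
                text, gen = " ".join(_plain(pool, 6)), None
            chem_sid = add_term(text, chem=True)
            plain_sid = add_term(text)
            truth.chem_pairs.append((rule, chem_sid, plain_sid))
            if gen is not None:
                expect_rewrite(plain_sid, rule, gen)
            else:
                truth.suppressions[plain_sid] = "S8"

    # --- engineered guard collisions -----------------------------------
    for _ in range(spec.homonym_collisions):
        a, b = _plain(pool, 2)
        sid = add_term(f"{a}, {b}")
        add_term(f"{b} {a}")  # other concept already holds the inversion
        truth.rewrites.setdefault(sid, []).append((1, f"{b} {a}"))
        truth.guard.append((sid, 1, f"{b} {a}", "skipped_homonym"))
    for _ in range(spec.duplicate_collisions):
        a, b = _plain(pool, 2)
        cid = new_cid()
        sid = add_term(f"{a}, {b}", cid=cid)
        add_term(f"{b} {a}", cid=cid)  # same concept already holds it
        truth.rewrites.setdefault(sid, []).append((1, f"{b} {a}"))
        truth.guard.append((sid, 1, f"{b} {a}", "skipped_duplicate"))

    # --- distractors: trigger nothing ----------------------------------
    for _ in range(spec.distractors):
        a, b = _plain(pool, 2)
        add_term(f"{a} {b}")

    semmap = SemanticTypeMap(
        concept_types={c: frozenset(ts) for c, ts in concept_types.items()},
        type_groups={CHEM_TYPE.lower(): "Chemicals & Drugs", PLAIN_TYPE.lower(): "Disorders"},
    )
    return Fixture(spec=spec, records=records, semmap=semmap, truth=truth)


# ---------------------------------------------------------------- corpus

_FILLER_SYLLABLES = ("zqa", "zqe", "zqi", "zqo", "zqu")


@dataclass
class CorpusFixture:
    documents: list[str]
    planted_counts: dict[str, int]
    planted_spans: list[tuple[int, int, int, str]]  # (doc_id, start, end, sid)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for doc in self.documents:
                fh.write(doc + "\n")
        return path


def _filler_word(rng: random.Random) -> str:
    return "".join(rng.choice(_FILLER_SYLLABLES) for _ in range(rng.randint(1, 2)))


def _vary_surface(text: str, rng: random.Random) -> str:
    """Case/punctuation variation within normalization equivalence."""
    choice = rng.randrange(4)
    if choice == 1:
        varied = text.upper()
    elif choice == 2:
        varied = text.lower()
    elif choice == 3:
        varied = text.replace(" ", "-")
    else:
        varied = text
    if tokenize(varied).texts() != tokenize(text).texts():
        return text  # variation altered the key; keep the original surface
    return varied


def generate_corpus(
    lexicon: Lexicon | Iterable[TermRecord],
    spec: FixtureSpec,
    planted: Mapping[str, int] | None = None,
) -> CorpusFixture:
    """Emit documents embedding lexicon terms at known positions.

    *planted* maps string_id → occurrence count; by default every record
    is planted ``spec.occurrences_per_term`` times.  Filler words come
    from a "zq"-prefixed alphabet disjoint from all lexicon keys, and a
    planted term's key may not contain any other indexed key as a proper
    contiguous subsequence — both checked here — so the planted counts
    are exactly what the recognizer must report.
    """
    rng = random.Random(spec.seed + 0x5EED)
    recs = list(lexicon)
    by_sid = {r.string_id: r for r in recs}
    index = build_index(recs)

    for key in index.keys():
        assert not any(tok.startswith("zq") for tok in key), "filler alphabet not disjoint"

    if planted is None:
        planted = {r.string_id: spec.occurrences_per_term for r in recs}

    instances: list[str] = []
    for sid, count in planted.items():
        rec = by_sid[sid]
        key = tuple(tokenize(rec.text).texts())
        if not key:
            raise ValueError(f"cannot plant {sid}: empty normalized key")
        for start in range(len(key)):
            for end in range(start + 1, len(key) + 1):
                if (end - start) < len(key) and index.lookup(key[start:end]):
                    raise ValueError(
                        f"cannot plant {sid}: nested indexed key {key[start:end]!r}"
                    )
        instances.extend([sid] * count)
    rng.shuffle(instances)

    n_docs = max(1, spec.n_documents)
    doc_tokens: list[list[str]] = [[] for _ in range(n_docs)]
    counts: dict[str, int] = {}
    spans: list[tuple[int, int, int, str]] = []
    for i, sid in enumerate(instances):
        doc_i = i % n_docs
        toks = doc_tokens[doc_i]
        if not toks or rng.random() < 0.8:
            toks.extend(_filler_word(rng) for _ in range(rng.randint(1, 2)))
        rec = by_sid[sid]
        surface = _vary_surface(rec.text, rng)
        key = tokenize(surface).texts()
        start = sum(len(tokenize(t).texts()) for t in toks)
        toks.append(surface)
        spans.append((doc_i + 1, start, start + len(key), sid))
        counts[sid] = counts.get(sid, 0) + 1
    for toks in doc_tokens:
        toks.append(_filler_word(rng))

    documents = [" ".join(toks) for toks in doc_tokens]
    spans.sort()
    return CorpusFixture(documents=documents, planted_counts=counts, planted_spans=spans)


# ------------------------------------------------------------- golden set

#: (rule_id, term, expected candidate texts, concept is Chemicals & Drugs)
GOLDEN_REWRITE_CASES: tuple = (
    (1, "Failure, Renal", ("Renal Failure",), False),
    (2, "Alzheimer's disease", ("Alzheimer disease",), False),
    (2, "Crohn's", ("Crohn",), False),
    (3, "Selective Serotonin Reuptake Inhibitors (SSRIs)",
     ("Selective Serotonin Reuptake Inhibitors", "SSRIs"), False),
    # Known-incorrect pairing the algorithm does produce, by design:
    (3, "Polibar Rapid (P/P)", ("Polibar Rapid", "P/P"), False),
    (4, "Chondria <beetle>", ("Chondria",), False),
    (4, "every <integer> weeks", ("every weeks",), False),
    (5, "Surgical intervention (finding)", ("Surgical intervention",), False),
    (5, "Heart (Body Part, Organ, or Organ Component)", ("Heart",), False),
    (6, "(protein) methionine-R-sulfoxide reductase",
     ("methionine-R-sulfoxide reductase",), False),
    (6, "(2-5')oligo(A) synthetase activity", ("oligo(A) synthetase activity",), False),
    (7, "[D]Respiratory abnormalities", ("Respiratory abnormalities",), False),
    (7, "[M]Lymphoid leukaemias", ("Lymphoid leukaemias",), False),
    # Known-incorrect but faithfully generated:
    (7, "[pyruvate dehydrogenase (lipoamide)] phosphatase activity",
     ("phosphatase activity",), False),
    (8, "Controls (Instrument)", ("Controls",), False),
    (8, "t(3;6)(p13;q25)", ("t(3;6)",), False),
    (8, "flagellar filament (sensu Bacteria)", ("flagellar filament",), False),
    (9, "Abstracts [Publication Type]", ("Abstracts",), False),
    (9, "Shigella flexneri 2a [II:3,4]", ("Shigella flexneri 2a",), False),
    (9, "Gluten-free foods [generic 1]", ("Gluten-free foods",), False),
)

#: Terms on which the named rule must emit nothing.
GOLDEN_NO_REWRITE_CASES: tuple = (
    (1, "Failure, Renal, Acute", False),      # two comma-space patterns
    (1, "Bandages, and dressings", False),    # contains a conjunction
    (2, "disease", False),
    (3, "treatment of pain (MI)", False),     # first letters differ
    (4, "<only>", False),                     # empty remainder
    (5, "Controls (Instrument)", False),      # not a semantic-type name
    (6, "(S)-ibuprofen", True),               # Chemicals & Drugs exclusion
    (8, "(S)-ibuprofen", True),
)

#: (rule_id, term) pairs the named suppression rule must remove.
GOLDEN_SUPPRESSION_CASES: tuple = (
    ("S1", "10*9/L"),
    ("S1", "WHILE"),
    ("S2", "Oxygen 2%"),
    ("S2", "Paracetamol 500 gram"),
    ("S3", "ADHESIVE @@ BANDAGE"),
    ("S4", "EC 2.7.1.112"),
    ("S4", "EC 2.7.1.-"),
    ("S5", "Unclassified sequences"),
    ("S5", "Injury, NEC"),
    ("S6", "Other and unspecified leukaemia"),
    ("S6", "Anemia, NOS"),
    ("S7", "Other"),
    ("S7", "Other diseases"),
    ("S8", "Head and Neck Squamous Cell Carcinoma"),
    ("S8", "insulin-like growth factor binding protein 1"),
)

#: (rule_id, term) pairs the named suppression rule must keep.
GOLDEN_KEPT_CASES: tuple = (
    ("S1", "protein X"),
    ("S2", "Vitamin B12"),
    ("S3", "bandage"),
    ("S4", "ECG 2.7"),
    ("S5", "NECROSIS"),
    ("S6", "DIAGNOSIS"),
    ("S7", "Mother"),
    ("S8", "Carcinoma of the Head"),
)


def golden_fixture() -> Fixture:
    """The frozen, non-random fixture of the worked examples.

    One concept per golden term; Chemicals & Drugs typing where the case
    requires it.  The ground truth lists the expected candidates and
    suppressions exactly as tabulated above.
    """
    truth = GroundTruth()
    records: list[TermRecord] = []
    concept_types: dict[str, frozenset[str]] = {}
    counter = 0
    seen_terms: dict[str, str] = {}

    def add(text: str, chem: bool) -> str:
        nonlocal counter
        if text in seen_terms:
            return seen_terms[text]
        counter += 1
        cid, sid = f"G{counter:03d}", f"GS{counter:03d}"
        concept_types[cid] = frozenset({CHEM_TYPE if chem else PLAIN_TYPE})
        records.append(TermRecord(concept_id=cid, string_id=sid, text=text))
        seen_terms[text] = sid
        return sid

    for rule, term, expected, chem in GOLDEN_REWRITE_CASES:
        sid = add(term, chem)
        for text in expected:
            truth.rewrites.setdefault(sid, []).append((rule, text))
    for rule, term, chem in GOLDEN_NO_REWRITE_CASES:
        add(term, chem)
    for rule, term in GOLDEN_SUPPRESSION_CASES:
        sid = add(term, False)
        truth.suppressions.setdefault(sid, rule)
    for rule, term in GOLDEN_KEPT_CASES:
        add(term, False)

    semmap = SemanticTypeMap(
        concept_types=concept_types,
        type_groups={CHEM_TYPE.lower(): "Chemicals & Drugs", PLAIN_TYPE.lower(): "Disorders"},
    )
    return Fixture(spec=None, records=records, semmap=semmap, truth=truth)
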