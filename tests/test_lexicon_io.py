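"""Concept-table and semantic-type table I/O, filtering, deduplication."""

import pytest

from lexiclean.lexicon_io import (
    Lexicon,
    LexiconFormatError,
    MRCONSO,
    REDUCED,
    TermRecord,
    deduplicate_within_concept,
    filter_default,
    read_concept_table,
    read_semantic_types,
    write_concept_table,
    write_suppressed_sidecar,
)


def _mrconso_row(cui="C0000001", lat="ENG", sui="S001", text="Renal Failure", sup="N"):
    fields = [""] * 18
    fields[0], fields[1], fields[5], fields[14], fields[16] = cui, lat, sui, text, sup
    return "|".join(fields) + "|"


def test_read_mrconso_extracts_fields(tmp_path):
    p = tmp_path / "conso.rrf"
    p.write_text(_mrconso_row() + "\n", encoding="utf-8")
    (rec,) = list(read_concept_table(p, MRCONSO))
    assert rec.concept_id == "C0000001"
    assert rec.string_id == "S001"
    assert rec.text == "Renal Failure"
    assert not rec.nlm_suppressible


def test_wrong_field_count_names_line(tmp_path):
    p = tmp_path / "bad.rrf"
    p.write_text(_mrconso_row() + "\n" + "C1|ENG|S2|N|five fields|\n", encoding="utf-8")
    with pytest.raises(LexiconFormatError, match="bad.rrf:2"):
        list(read_concept_table(p, MRCONSO))


def test_empty_file_yields_empty_stream(tmp_path):
    p = tmp_path / "empty.rrf"
    p.write_text("", encoding="utf-8")
    assert list(read_concept_table(p, REDUCED)) == []


@pytest.mark.parametrize(
    ("length", "kept"), [(254, True), (255, True), (256, False)]
)
def test_length_filter_boundary(length, kept):
    rec = TermRecord(concept_id="C1", string_id="S1", text="x" * length)
    assert (list(filter_default([rec])) == [rec]) is kept


def test_filter_drops_suppressible_and_non_english():
    recs = [
        TermRecord(concept_id="C1", string_id="S1", text="keep me"),
        TermRecord(concept_id="C1", string_id="S2", text="weg damit", language="GER"),
        TermRecord(concept_id="C1", string_id="S3", text="hidden", nlm_suppressible=True),
    ]
    assert [r.string_id for r in filter_default(recs)] == ["S1"]


def test_dedup_within_concept_first_wins_and_homonyms_survive():
    recs = [
        TermRecord(concept_id="C1", string_id="S1", text="Renal Failure"),
        TermRecord(concept_id="C1", string_id="S2", text="renal-failure"),
        TermRecord(concept_id="C2", string_id="S3", text="renal failure"),
        TermRecord(concept_id="C3", string_id="S4", text="solo term"),
    ]
    lex = deduplicate_within_concept(recs)
    assert [r.string_id for r in lex] == ["S1", "S3", "S4"]
    # cross-concept duplicate kept: both concepts hold the shared key
    assert lex.concepts_for_key("renal failure") == {"C1", "C2"}


def test_dedup_idempotent_and_keys_pairwise_distinct(small_fixture):
    lex = deduplicate_within_concept(small_fixture.records)
    again = deduplicate_within_concept(lex)
    assert [r.string_id for r in again] == [r.string_id for r in lex]
    per_concept = {}
    for rec in lex:
        keys = per_concept.setdefault(rec.concept_id, set())
        assert rec.key not in keys
        keys.add(rec.key)


def test_lexicon_rejects_same_concept_duplicate_key():
    lex = Lexicon()
    lex.add(TermRecord(concept_id="C1", string_id="S1", text="Renal Failure"))
    with pytest.raises(ValueError, match="already holds"):
        lex.add(TermRecord(concept_id="C1", string_id="S2", text="renal failure"))


def test_round_trip_byte_identical(tmp_path):
    rows = [
        _mrconso_row(),
        _mrconso_row(cui="C0000002", sui="S002", text="Failure, Renal"),
    ]
    src = tmp_path / "in.rrf"
    src.write_text("\n".join(rows) + "\n", encoding="utf-8")
    lex = deduplicate_within_concept(filter_default(read_concept_table(src, MRCONSO)))
    dst = tmp_path / "out.rrf"
    write_concept_table(lex, dst, MRCONSO)
    assert dst.read_bytes() == src.read_bytes()


def test_generated_rows_and_sidecar(tmp_path):
    original = TermRecord(concept_id="C1", string_id="S1", text="Failure, Renal")
    generated = TermRecord(
        concept_id="C1", string_id="R1-1", text="Renal Failure",
        provenance="generated", rule_id="1",
    )
    out = tmp_path / "out.rrf"
    write_concept_table([original, generated], out, REDUCED)
    lines = out.read_text(encoding="utf-8").splitlines()
    assert lines == ["C1|ENG|S1|N|Failure, Renal|", "C1|ENG|R1-1|N|Renal Failure|"]

    side = tmp_path / "out.suppressed"
    write_suppressed_sidecar([(original, "S3")], side, REDUCED)
    assert side.read_text(encoding="utf-8") == "C1|ENG|S1|N|Failure, Renal|S3|\n"


def test_semantic_types_any_semantics(tmp_path):
    sty = tmp_path / "sty.rrf"
    sty.write_text(
        "C1|T121|A1|Pharmacologic Substance|\n"
        "C2|T033|A2|Finding|\nC2|T195|A3|Antibiotic|\n"
        "C3|T999|A4|Imaginary Type|\n",
        encoding="utf-8",
    )
    groups = tmp_path / "groups.txt"
    groups.write_text(
        "CHEM|Chemicals & Drugs|T121|Pharmacologic Substance\n"
        "CHEM|Chemicals & Drugs|T195|Antibiotic\n"
        "DISO|Disorders|T033|Finding\n",
        encoding="utf-8",
    )
    semmap = read_semantic_types(sty, groups)
    assert semmap.in_group("C1", "Chemicals & Drugs")
    # ANY semantics: one chemical type suffices
    assert semmap.in_group("C2", "Chemicals & Drugs")
    assert semmap.in_group("C2", "Disorders")
    # unmapped type -> sentinel group; absent concept -> no groups
    assert semmap.groups_of("C3") == {"ungrouped"}
    assert not semmap.in_group("C99", "Chemicals & Drugs")


def test_malformed_semantic_rows_name_line(tmp_path):
    sty = tmp_path / "sty.rrf"
    sty.write_text("C1|T121\n", encoding="utf-8")
    groups = tmp_path / "groups.txt"
    groups.write_text("CHEM|Chemicals & Drugs|T121|Pharmacologic Substance\n", encoding="utf-8")
    with pytest.raises(LexiconFormatError, match="sty.rrf:1"):
        read_semantic_types(sty, groups)
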