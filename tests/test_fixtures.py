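"""The synthetic fixture generator is itself first-class, tested code."""

import pytest

from lexiclean.engine import (
    apply_rules,
    rewrite_term,
    single_rule_delta,
    suppression_verdict,
)
from lexiclean.fixtures import (
    ALL_RULE_IDS,
    FixtureSpec,
    generate_corpus,
    generate_lexicon,
    golden_fixture,
)
from lexiclean.normalization import tokenize
from lexiclean.recognizer import annotate, build_index, corpus_stats


def test_determinism_same_seed_identical_outputs(tmp_path):
    a = generate_lexicon(FixtureSpec(seed=42))
    b = generate_lexicon(FixtureSpec(seed=42))
    assert [(r.string_id, r.concept_id, r.text) for r in a.records] == [
        (r.string_id, r.concept_id, r.text) for r in b.records
    ]
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for name in pa:
        assert pa[name].read_bytes() == pb[name].read_bytes()
    ca = generate_corpus(a.records, a.spec)
    cb = generate_corpus(b.records, b.spec)
    assert ca.documents == cb.documents
    c = generate_lexicon(FixtureSpec(seed=43))
    assert [r.text for r in c.records] != [r.text for r in a.records]


def test_ground_truth_matches_rule_modules():
    """The generator's expected firings (built from templates, not by
    calling the rules) must equal the actual rule outputs — the
    integration surface between fixtures and rule code."""
    fx = generate_lexicon(FixtureSpec(seed=2))
    by_sid = {r.string_id: r for r in fx.records}
    chem_sids = {
        r.string_id
        for r in fx.records
        if fx.semmap.in_group(r.concept_id, "Chemicals & Drugs")
    }
    for sid, expected in fx.truth.rewrites.items():
        rec = by_sid[sid]
        for rule, text in expected:
            got = rewrite_term(rule, rec.text, in_chem_group=sid in chem_sids)
            assert text in got, (rule, rec.text, got)
    for sid, rule in fx.truth.suppressions.items():
        rec = by_sid[sid]
        verdict = suppression_verdict(rule, rec.text, in_chem_group=sid in chem_sids)
        assert verdict.suppressed, (rule, rec.text)


def test_one_term_per_category_fires_each_rule_exactly_once():
    fx = generate_lexicon(
        FixtureSpec(seed=9, distractors=0, homonym_collisions=0,
                    duplicate_collisions=0, chem_exclusion_pairs=0)
    )
    lex = fx.lexicon()
    assert len(lex) == len(ALL_RULE_IDS)
    for rid in ALL_RULE_IDS:
        result = single_rule_delta(lex, fx.semmap, rid)
        tally = result.report[rid]
        if isinstance(rid, int):
            expected = 2 if rid == 3 else 1  # short/long form emits both forms
            assert tally.added == expected, rid
        else:
            assert tally.suppressed == 1, rid


def test_homonym_and_duplicate_collisions(full_profile):
    fx = generate_lexicon(FixtureSpec(seed=4, homonym_collisions=2, duplicate_collisions=2))
    result = apply_rules(fx.lexicon(), fx.semmap, full_profile)
    actions = {
        (ev.source_string_id, ev.rule_id, ev.text): ev.action for ev in result.events
    }
    for sid, rule, text, expected in fx.truth.guard:
        assert actions[(sid, rule, text)] == expected, (sid, text)
    assert sum(1 for a in actions.values() if a == "skipped_homonym") == 2
    assert sum(1 for a in actions.values() if a == "skipped_duplicate") == 2


def test_filler_vocabulary_disjoint_from_lexicon_keys():
    fx = generate_lexicon(FixtureSpec(seed=6))
    corpus = generate_corpus(fx.records, fx.spec)
    index = build_index(fx.records)
    lexicon_tokens = {tok for key in index.keys() for tok in key}
    for doc in corpus.documents:
        for tok in tokenize(doc).texts():
            if tok.startswith("zq"):
                assert tok not in lexicon_tokens


def test_planted_spans_are_found_exactly():
    spec = FixtureSpec(seed=13, occurrences_per_term=2)
    fx = generate_lexicon(spec)
    index = build_index(fx.records)
    # plant only records whose key is unique in the index (the chemical
    # twins share their text across two concepts by design)
    planted = {
        r.string_id: 2
        for r in fx.records
        if len(index.lookup(tuple(tokenize(r.text).texts()))) == 1
    }
    corpus = generate_corpus(fx.records, spec, planted)
    stats = corpus_stats(corpus.documents, index)
    assert stats.occurrences == sum(corpus.planted_counts.values())
    by_sid = {r.string_id: r for r in fx.records}
    assert dict(stats.per_record) == {
        (by_sid[sid].concept_id, sid): n for sid, n in corpus.planted_counts.items()
    }
    found_spans = {
        (doc_id, ev.start, ev.end)
        for doc_id, doc in enumerate(corpus.documents, start=1)
        for ev in annotate(doc, index, doc_id)
    }
    assert {(d, s, e) for d, s, e, _ in corpus.planted_spans} == found_spans


def test_nested_planting_rejected():
    spec = FixtureSpec(seed=1)
    fx = generate_lexicon(spec)
    from lexiclean.lexicon_io import TermRecord

    records = fx.records + [
        TermRecord(concept_id="CN", string_id="SN1", text="outer inner words"),
        TermRecord(concept_id="CN2", string_id="SN2", text="inner"),
    ]
    with pytest.raises(ValueError, match="nested"):
        generate_corpus(records, spec, {"SN1": 1})


def test_golden_fixture_is_frozen_and_consistent():
    g1, g2 = golden_fixture(), golden_fixture()
    assert [(r.string_id, r.text) for r in g1.records] == [
        (r.string_id, r.text) for r in g2.records
    ]
    assert g1.truth.rewrites and g1.truth.suppressions
    # one concept per distinct term, chemical typing where required
    ibuprofen = next(r for r in g1.records if r.text == "(S)-ibuprofen")
    assert g1.semmap.in_group(ibuprofen.concept_id, "Chemicals & Drugs")
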