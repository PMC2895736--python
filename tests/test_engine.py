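"""Pipeline orchestration: guard, conservation, determinism, reports."""

import pytest

from lexiclean.engine import (
    ADDED,
    ConfigError,
    PROFILES,
    RuleConfig,
    SKIPPED_DUPLICATE,
    SKIPPED_EMPTY,
    SKIPPED_HOMONYM,
    apply_rules,
    guard_candidate,
    single_rule_delta,
)
from lexiclean.fixtures import FixtureSpec, generate_lexicon
from lexiclean.lexicon_io import SemanticTypeMap, TermRecord, deduplicate_within_concept
from lexiclean.rewrite_rules import RewriteCandidate

EMPTY_SEMMAP = SemanticTypeMap()


def _lex(*terms):
    return deduplicate_within_concept(
        TermRecord(concept_id=c, string_id=f"S{i}", text=t)
        for i, (c, t) in enumerate(terms)
    )


def test_guard_distinguishes_duplicate_homonym_added():
    lex = _lex(("C1", "renal failure"), ("C2", "heart attack"))
    cand = RewriteCandidate(rule_id=1, text="Renal Failure")
    assert guard_candidate(cand, "C1", lex) == SKIPPED_DUPLICATE
    assert guard_candidate(cand, "C2", lex) == SKIPPED_HOMONYM
    unseen = RewriteCandidate(rule_id=1, text="Cardiac Arrest")
    assert guard_candidate(unseen, "C2", lex) == ADDED
    assert guard_candidate(RewriteCandidate(rule_id=1, text="@@"), "C1", lex) == SKIPPED_EMPTY


def test_apply_rules_adds_inversion_and_respects_guard(recommended):
    lex = _lex(("C1", "Failure, Renal"))
    result = apply_rules(lex, EMPTY_SEMMAP, recommended)
    assert [r.text for r in result.lexicon] == ["Failure, Renal", "Renal Failure"]
    gen = result.lexicon["R1-1"]
    assert gen.provenance == "generated" and gen.rule_id == "1"

    lex2 = _lex(("C1", "Failure, Renal"), ("C2", "Renal Failure"))
    result2 = apply_rules(lex2, EMPTY_SEMMAP, recommended)
    assert sum(1 for r in result2.lexicon if r.concept_id == "C1") == 1
    assert result2.report[1].homonyms == 1
    assert result2.report[1].homonym_pct == 100.0


def test_empty_rule_list_is_identity(small_fixture):
    lex = small_fixture.lexicon()
    config = RuleConfig(rewrite_rules=(), suppression_rules=(), profile="none")
    result = apply_rules(lex, small_fixture.semmap, config)
    assert [r.string_id for r in result.lexicon] == [r.string_id for r in lex]


def test_conservation_identity(small_fixture, full_profile):
    result = apply_rules(small_fixture.lexicon(), small_fixture.semmap, full_profile)
    assert len(result.lexicon) == (
        result.n_input + result.report.total_added - result.report.total_suppressed
    )
    # and the event log agrees with the report tallies
    added = sum(1 for ev in result.events if ev.action == ADDED)
    suppressed = sum(1 for ev in result.events if ev.action == "suppressed")
    assert added == result.report.total_added
    assert suppressed == result.report.total_suppressed


def test_guard_correctness_no_same_concept_key_collisions(small_fixture, full_profile):
    result = apply_rules(small_fixture.lexicon(), small_fixture.semmap, full_profile)
    seen = set()
    for rec in result.lexicon:
        assert (rec.concept_id, rec.key) not in seen
        seen.add((rec.concept_id, rec.key))


def test_determinism(small_fixture, full_profile):
    lex = small_fixture.lexicon()
    r1 = apply_rules(lex, small_fixture.semmap, full_profile)
    r2 = apply_rules(lex, small_fixture.semmap, full_profile)
    assert [(e.rule_id, e.source_string_id, e.action, e.text) for e in r1.events] == [
        (e.rule_id, e.source_string_id, e.action, e.text) for e in r2.events
    ]
    assert r1.report.to_tsv() == r2.report.to_tsv()
    assert [(r.string_id, r.text) for r in r1.lexicon] == [
        (r.string_id, r.text) for r in r2.lexicon
    ]


def test_input_lexicon_never_mutated(small_fixture, full_profile):
    lex = small_fixture.lexicon()
    before = [r.string_id for r in lex]
    apply_rules(lex, small_fixture.semmap, full_profile)
    assert [r.string_id for r in lex] == before


def test_guarded_idempotence(small_fixture, recommended):
    first = apply_rules(small_fixture.lexicon(), small_fixture.semmap, recommended)
    second = apply_rules(first.lexicon, small_fixture.semmap, recommended)
    assert second.report.total_added == 0
    assert second.report.total_suppressed == 0


def test_single_rule_deltas_sum_to_full_pipeline():
    """On a fixture where each term triggers exactly one rule, the full
    report equals the sum of the per-rule deltas."""
    fx = generate_lexicon(FixtureSpec(seed=23, distractors=3,
                                      homonym_collisions=0, duplicate_collisions=0,
                                      chem_exclusion_pairs=0))
    lex = fx.lexicon()
    full = apply_rules(lex, fx.semmap, RuleConfig.from_profile("full"))
    for rid, tally in full.report.rules.items():
        delta = single_rule_delta(lex, fx.semmap, rid)
        assert delta.report[rid].added == tally.added, rid
        assert delta.report[rid].suppressed == tally.suppressed, rid


def test_single_rule_delta_counts(small_fixture):
    at_sign_terms = [
        sid for sid, rid in small_fixture.truth.suppressions.items() if rid == "S3"
    ]
    result = single_rule_delta(small_fixture.lexicon(), small_fixture.semmap, "S3")
    assert result.report["S3"].suppressed == len(at_sign_terms)


def test_review_flag_on_rules_3_and_4(golden, full_profile):
    result = apply_rules(golden.lexicon(), golden.semmap, full_profile)
    for ev in result.events:
        if ev.rule_id in (3, 4) and ev.action == ADDED:
            assert ev.review
        if ev.rule_id in (1, 2, 5):
            assert not ev.review


def test_config_validation():
    with pytest.raises(ConfigError, match="unknown rewrite"):
        RuleConfig(rewrite_rules=(1, 42), suppression_rules=())
    with pytest.raises(ConfigError, match="unknown suppression"):
        RuleConfig(rewrite_rules=(), suppression_rules=("S9",))
    with pytest.raises(ConfigError, match="duplicate"):
        RuleConfig(rewrite_rules=(1, 1), suppression_rules=())
    with pytest.raises(ConfigError, match="unknown profile"):
        RuleConfig.from_profile("bogus")


def test_missing_resource_fails_before_processing(small_fixture):
    config = RuleConfig(stopwords_path="/nonexistent/stopwords.txt")
    with pytest.raises(ConfigError, match="resource"):
        apply_rules(small_fixture.lexicon(), small_fixture.semmap, config)


def test_yaml_config_roundtrip(tmp_path):
    cfg_file = tmp_path / "rules.yaml"
    cfg_file.write_text(
        "profile: full\nrules: [1, 2, S3]\noutput:\n  suppressed_sidecar: false\n",
        encoding="utf-8",
    )
    config = RuleConfig.from_yaml(cfg_file)
    assert config.rewrite_rules == (1, 2)
    assert config.suppression_rules == ("S3",)
    assert not config.suppressed_sidecar

    bad = tmp_path / "bad.yaml"
    bad.write_text("rules: [Q7]\n", encoding="utf-8")
    with pytest.raises(ConfigError):
        RuleConfig.from_yaml(bad)


def test_profiles_shape():
    rw, sp = PROFILES["recommended"]
    assert rw == (1, 2, 3, 4, 5)
    assert sp == ("S1", "S2", "S3", "S4", "S5", "S6", "S7")
    rw_full, sp_full = PROFILES["full"]
    assert len(rw_full) == 9 and len(sp_full) == 8
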