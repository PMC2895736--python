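"""Pipeline orchestration: filter, dedup, rewrite with guard, suppress.

The pipeline order is fixed:

1. default extraction filters (English, not NLM-suppressible, ≤255 chars);
2. within-concept deduplication on the shared normal form;
3. the enabled rewrite rules, in id order, over all *original* terms —
   every candidate passes the duplicate/homonym guard and is vetted
   against the enabled suppression rules before being added (a candidate
   a suppression rule would remove is never added in the first place,
   which makes the whole pipeline idempotent);
4. the enabled suppression rules, in id order, over the remaining records.

Every rule-application outcome is logged as a :class:`RuleEvent`; the
per-rule :class:`RuleReport` is tallied from the event log and the
conservation identity ``|output| = |deduplicated input| + added −
suppressed`` holds on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import resources as _res
from .lexicon_io import (
    Lexicon,
    SemanticTypeMap,
    TermRecord,
    deduplicate_within_concept,
    filter_default,
)
from .normalization import normalize_key
from .rewrite_rules import (
    REVIEW_RULES,
    REWRITE_RULE_NAMES,
    RewriteCandidate,
    rw_angular_brackets,
    rw_begin_brackets,
    rw_begin_parentheses,
    rw_end_brackets,
    rw_end_parentheses,
    rw_possessives,
    rw_semantic_type,
    rw_short_long_form,
    rw_syntactic_inversion,
)
from .suppression_rules import (
    SUPPRESSION_RULE_NAMES,
    SuppressionVerdict,
    sp_any_classification,
    sp_any_underspecification,
    sp_at_sign,
    sp_dosages,
    sp_ec_number,
    sp_miscellaneous,
    sp_short_token,
    sp_words_gt5,
)

__all__ = [
    "RuleConfig",
    "RuleResources",
    "RuleEvent",
    "RuleReport",
    "PipelineResult",
    "ConfigError",
    "guard_candidate",
    "apply_rules",
    "single_rule_delta",
    "rewrite_term",
    "suppression_verdict",
    "default_resources",
    "PROFILES",
]

ADDED = "added"
SUPPRESSED = "suppressed"
SKIPPED_DUPLICATE = "skipped_duplicate"
SKIPPED_HOMONYM = "skipped_homonym"
SKIPPED_EMPTY = "skipped_empty"
SKIPPED_SUPPRESSED = "skipped_suppressed"

ALL_REWRITE_IDS = tuple(sorted(REWRITE_RULE_NAMES))
ALL_SUPPRESSION_IDS = tuple(sorted(SUPPRESSION_RULE_NAMES))

#: Named rule profiles.  "recommended" is the subset that survives manual
#: evaluation: rewrite rules 1-5 and suppression rules S1-S7 (the
#: words>5 rule and the four parenthetical rewrite rules are excluded).
PROFILES: dict[str, tuple[tuple[int, ...], tuple[str, ...]]] = {
    "recommended": ((1, 2, 3, 4, 5), ("S1", "S2", "S3", "S4", "S5", "S6", "S7")),
    "full": (ALL_REWRITE_IDS, ALL_SUPPRESSION_IDS),
}


class ConfigError(ValueError):
    """Invalid rule configuration (unknown rule id, missing resource …)."""


@dataclass(frozen=True)
class RuleResources:
    """Loaded word lists shared by the rules."""

    stopwords: frozenset[str]
    type_names: frozenset[str]
    prepositions: frozenset[str]
    units: frozenset[str]

    @classmethod
    def load(
        cls,
        stopwords_path: str | None = None,
        semantic_types_path: str | None = None,
        prepositions_path: str | None = None,
        units: Iterable[str] | None = None,
    ) -> "RuleResources":
        try:
            return cls(
                stopwords=_res.load_stopwords(stopwords_path),
                type_names=_res.load_semantic_type_names(semantic_types_path),
                prepositions=_res.load_prepositions(prepositions_path),
                units=frozenset(u.lower() for u in units) if units is not None else _res.DEFAULT_UNITS,
            )
        except OSError as exc:
            raise ConfigError(f"cannot load rule resource: {exc}") from exc


@dataclass
class RuleConfig:
    """Enabled rules, their resources, and output options."""

    rewrite_rules: tuple[int, ...] = PROFILES["recommended"][0]
    suppression_rules: tuple[str, ...] = PROFILES["recommended"][1]
    profile: str = "recommended"
    stopwords_path: str | None = None
    semantic_types_path: str | None = None
    prepositions_path: str | None = None
    units: tuple[str, ...] | None = None
    apply_default_filters: bool = True
    homonym_sidecar: bool = False
    suppressed_sidecar: bool = True

    def __post_init__(self):
        seen: set = set()
        for rid in list(self.rewrite_rules) + list(self.suppression_rules):
            if rid in seen:
                raise ConfigError(f"duplicate rule id {rid!r}")
            seen.add(rid)
        for rid in self.rewrite_rules:
            if rid not in REWRITE_RULE_NAMES:
                raise ConfigError(f"unknown rewrite rule id {rid!r}")
        for rid in self.suppression_rules:
            if rid not in SUPPRESSION_RULE_NAMES:
                raise ConfigError(f"unknown suppression rule id {rid!r}")

    @classmethod
    def from_profile(cls, name: str, **kwargs) -> "RuleConfig":
        if name not in PROFILES:
            raise ConfigError(f"unknown profile {name!r}; known: {sorted(PROFILES)}")
        rw, sp = PROFILES[name]
        return cls(rewrite_rules=rw, suppression_rules=sp, profile=name, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        """Load a YAML configuration file.

        Recognised keys: ``profile`` (name), ``rules`` (explicit list of
        rule ids, overriding the profile), ``resources`` (mapping with
        ``stopwords``, ``semantic_types``, ``prepositions`` paths and a
        ``units`` list), ``output`` (``suppressed_sidecar``,
        ``homonym_sidecar`` flags), ``apply_default_filters``.
        """
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        profile = doc.get("profile", "recommended")
        if profile not in PROFILES:
            raise ConfigError(f"{path}: unknown profile {profile!r}")
        rw, sp = PROFILES[profile]
        if "rules" in doc:
            rw_l: list[int] = []
            sp_l: list[str] = []
            for rid in doc["rules"]:
                if isinstance(rid, int):
                    rw_l.append(rid)
                elif isinstance(rid, str) and rid.upper().startswith("S"):
                    sp_l.append(rid.upper())
                else:
                    raise ConfigError(f"{path}: unknown rule id {rid!r}")
            rw, sp = tuple(rw_l), tuple(sp_l)
        res = doc.get("resources", {}) or {}
        out = doc.get("output", {}) or {}
        units = res.get("units")
        return cls(
            rewrite_rules=rw,
            suppression_rules=sp,
            profile=profile,
            stopwords_path=res.get("stopwords"),
            semantic_types_path=res.get("semantic_types"),
            prepositions_path=res.get("prepositions"),
            units=tuple(units) if units else None,
            apply_default_filters=bool(doc.get("apply_default_filters", True)),
            homonym_sidecar=bool(out.get("homonym_sidecar", False)),
            suppressed_sidecar=bool(out.get("suppressed_sidecar", True)),
        )

    def load_resources(self) -> RuleResources:
        return RuleResources.load(
            self.stopwords_path,
            self.semantic_types_path,
            self.prepositions_path,
            self.units,
        )


@dataclass(frozen=True)
class RuleEvent:
    """One audit entry per rule-application outcome (append-only)."""

    rule_id: int | str
    source_string_id: str | None
    action: str
    text: str | None = None
    detail: str = ""
    review: bool = False


@dataclass
class _RuleTally:
    added: int = 0
    suppressed: int = 0
    skipped_duplicate: int = 0
    skipped_homonym: int = 0
    skipped_empty: int = 0
    skipped_suppressed: int = 0

    @property
    def homonyms(self) -> int:
        return self.skipped_homonym

    @property
    def homonym_pct(self) -> float:
        denom = self.added + self.skipped_homonym
        return 100.0 * self.skipped_homonym / denom if denom else 0.0


class RuleReport:
    """Per-rule counts of generated, suppressed, and guarded-out terms."""

    def __init__(self, rule_ids: Sequence[int | str]):
        self.rules: dict[int | str, _RuleTally] = {rid: _RuleTally() for rid in rule_ids}

    def tally(self, event: RuleEvent) -> None:
        t = self.rules[event.rule_id]
        setattr(t, event.action, getattr(t, event.action) + 1)

    def __getitem__(self, rule_id) -> _RuleTally:
        return self.rules[rule_id]

    @property
    def total_added(self) -> int:
        return sum(t.added for t in self.rules.values())

    @property
    def total_suppressed(self) -> int:
        return sum(t.suppressed for t in self.rules.values())

    def rows(self) -> list[tuple]:
        out = []
        for rid, t in self.rules.items():
            name = REWRITE_RULE_NAMES.get(rid) or SUPPRESSION_RULE_NAMES.get(rid)
            out.append((rid, name, t.added, t.suppressed, t.homonyms, round(t.homonym_pct, 1)))
        return out

    def to_tsv(self) -> str:
        lines = ["rule_id\trule\tadded\tsuppressed\thomonyms\thomonym_pct"]
        for row in self.rows():
            lines.append("\t".join(str(x) for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    lexicon: Lexicon
    report: RuleReport
    events: list[RuleEvent]
    suppressed: list[tuple[TermRecord, str]]  # (record, suppressing rule id)
    homonyms: list[tuple[RewriteCandidate, str]]  # (candidate, concept_id)
    n_input: int


def guard_candidate(
    candidate: RewriteCandidate,
    concept_id: str,
    lexicon: Lexicon,
) -> str:
    """Duplicate/homonym guard for one rewrite candidate.

    A new term is not added if its normalized key can already be found
    among the synonyms of the same concept (``skipped_duplicate``) or of
    any other concept (``skipped_homonym``); keys that normalize to the
    empty string are ``skipped_empty``.  Otherwise the candidate may be
    ``added``.
    """
    key = normalize_key(candidate.text)
    if not key:
        return SKIPPED_EMPTY
    concepts = lexicon.concepts_for_key(key)
    if concept_id in concepts:
        return SKIPPED_DUPLICATE
    if concepts:
        return SKIPPED_HOMONYM
    return ADDED


def _rewrite_candidates(
    rule_id: int,
    rec: TermRecord,
    in_chem: bool,
    res: RuleResources,
) -> list[RewriteCandidate]:
    term, sid = rec.text, rec.string_id
    if rule_id == 1:
        return rw_syntactic_inversion(term, res.prepositions, sid)
    if rule_id == 2:
        return rw_possessives(term, sid)
    if rule_id == 3:
        return rw_short_long_form(term, sid)
    if rule_id == 4:
        return rw_angular_brackets(term, sid)
    if rule_id == 5:
        return rw_semantic_type(term, res.type_names, sid)
    if rule_id == 6:
        return rw_begin_parentheses(term, in_chem, sid)
    if rule_id == 7:
        return rw_begin_brackets(term, in_chem, sid)
    if rule_id == 8:
        return rw_end_parentheses(term, in_chem, sid)
    if rule_id == 9:
        return rw_end_brackets(term, in_chem, sid)
    raise ConfigError(f"unknown rewrite rule id {rule_id!r}")


def _suppression_verdict(
    rule_id: str,
    text: str,
    in_chem: bool,
    res: RuleResources,
    sid: str | None = None,
) -> SuppressionVerdict:
    if rule_id == "S1":
        return sp_short_token(text, res.stopwords, sid)
    if rule_id == "S2":
        return sp_dosages(text, res.units, sid)
    if rule_id == "S3":
        return sp_at_sign(text, sid)
    if rule_id == "S4":
        return sp_ec_number(text, sid)
    if rule_id == "S5":
        return sp_any_classification(text, sid)
    if rule_id == "S6":
        return sp_any_underspecification(text, sid)
    if rule_id == "S7":
        return sp_miscellaneous(text, sid)
    if rule_id == "S8":
        return sp_words_gt5(text, in_chem, sid)
    raise ConfigError(f"unknown suppression rule id {rule_id!r}")


def _as_lexicon(source, apply_filters: bool) -> Lexicon:
    if isinstance(source, Lexicon):
        # Work on a copy; the caller's lexicon is never mutated.
        lex = Lexicon()
        for rec in source:
            lex.add(rec)
        return lex
    records = filter_default(source) if apply_filters else source
    return deduplicate_within_concept(records)


def apply_rules(
    lexicon: Lexicon | Iterable[TermRecord],
    semmap: SemanticTypeMap,
    config: RuleConfig,
) -> PipelineResult:
    """Run the full pipeline and return the output lexicon plus audit data.

    *lexicon* may be a prepared :class:`Lexicon` (already filtered and
    deduplicated) or a raw record stream, in which case the default
    filters and within-concept deduplication run first.
    """
    res = config.load_resources()  # fails before any processing
    lex = _as_lexicon(lexicon, config.apply_default_filters)
    n_input = len(lex)

    all_ids = list(config.rewrite_rules) + list(config.suppression_rules)
    report = RuleReport(all_ids)
    events: list[RuleEvent] = []
    suppressed: list[tuple[TermRecord, str]] = []
    homonym_log: list[tuple[RewriteCandidate, str]] = []

    chem = _res.CHEMICALS_AND_DRUGS
    in_chem = {cid: semmap.in_group(cid, chem) for cid in lex.concept_ids()}

    # --- rewrite pass over the original terms (no cascading) ----------
    originals = lex.records()
    counters = {rid: 0 for rid in config.rewrite_rules}
    for rule_id in sorted(config.rewrite_rules):
        review = rule_id in REVIEW_RULES
        for rec in originals:
            cands = _rewrite_candidates(rule_id, rec, in_chem.get(rec.concept_id, False), res)
            for cand in cands:
                action = guard_candidate(cand, rec.concept_id, lex)
                detail = ""
                if action == ADDED:
                    veto = _vet_candidate(cand, rec, in_chem, res, config)
                    if veto is not None:
                        action = SKIPPED_SUPPRESSED
                        detail = veto
                if action == ADDED:
                    counters[rule_id] += 1
                    gen_sid = f"R{rule_id}-{counters[rule_id]}"
                    lex.add(
                        TermRecord(
                            concept_id=rec.concept_id,
                            string_id=gen_sid,
                            text=cand.text,
                            language=rec.language,
                            source_vocab=rec.source_vocab,
                            term_type=rec.term_type,
                            provenance="generated",
                            rule_id=str(rule_id),
                        )
                    )
                elif action == SKIPPED_HOMONYM:
                    homonym_log.append((cand, rec.concept_id))
                events.append(
                    RuleEvent(rule_id, rec.string_id, action, cand.text, detail, review)
                )
                report.tally(events[-1])

    # --- suppression pass over original and generated terms -----------
    for rec in lex.records():
        for rule_id in sorted(config.suppression_rules):
            verdict = _suppression_verdict(
                rule_id, rec.text, in_chem.get(rec.concept_id, False), res, rec.string_id
            )
            if verdict.suppressed:
                lex.remove(rec.string_id)
                suppressed.append((rec, rule_id))
                events.append(
                    RuleEvent(rule_id, rec.string_id, SUPPRESSED, rec.text, verdict.trigger)
                )
                report.tally(events[-1])
                break

    return PipelineResult(lex, report, events, suppressed, homonym_log, n_input)


def _vet_candidate(
    cand: RewriteCandidate,
    rec: TermRecord,
    in_chem: dict[str, bool],
    res: RuleResources,
    config: RuleConfig,
) -> str | None:
    """Return the id of the enabled suppression rule that would remove the
    candidate, or None if it may be added."""
    for rule_id in sorted(config.suppression_rules):
        verdict = _suppression_verdict(
            rule_id, cand.text, in_chem.get(rec.concept_id, False), res
        )
        if verdict.suppressed:
            return rule_id
    return None


_DEFAULT_RESOURCES: list = []


def default_resources() -> RuleResources:
    """The vendored resource lists, loaded once."""
    if not _DEFAULT_RESOURCES:
        _DEFAULT_RESOURCES.append(RuleResources.load())
    return _DEFAULT_RESOURCES[0]


def rewrite_term(
    rule_id: int,
    term: str,
    in_chem_group: bool = False,
    resources: RuleResources | None = None,
) -> list[str]:
    """Candidate texts one rewrite rule emits for a bare term string."""
    rec = TermRecord(concept_id="C0", string_id="S0", text=term)
    res = resources or default_resources()
    return [c.text for c in _rewrite_candidates(rule_id, rec, in_chem_group, res)]


def suppression_verdict(
    rule_id: str,
    term: str,
    in_chem_group: bool = False,
    resources: RuleResources | None = None,
) -> SuppressionVerdict:
    """Verdict of one suppression rule on a bare term string."""
    res = resources or default_resources()
    return _suppression_verdict(rule_id, term, in_chem_group, res)


def single_rule_delta(
    lexicon: Lexicon | Iterable[TermRecord],
    semmap: SemanticTypeMap,
    rule_id: int | str,
    base_config: RuleConfig | None = None,
) -> PipelineResult:
    """Run the pipeline with only *rule_id* enabled (each rule is
    evaluated separately)."""
    base = base_config or RuleConfig()
    if isinstance(rule_id, int):
        cfg_kwargs = dict(rewrite_rules=(rule_id,), suppression_rules=())
    else:
        cfg_kwargs = dict(rewrite_rules=(), suppression_rules=(rule_id,))
    config = RuleConfig(
        profile="single",
        stopwords_path=base.stopwords_path,
        semantic_types_path=base.semantic_types_path,
        prepositions_path=base.prepositions_path,
        units=base.units,
        apply_default_filters=base.apply_default_filters,
        **cfg_kwargs,
    )
    return apply_rules(lexicon, semmap, config)
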