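"""The nine synonym-generating rewrite rules.

Each rule consumes one term string (plus, for some rules, semantic
context) and returns zero or more candidate new strings.  Candidates are
raw proposals: the duplicate/homonym guard in the rule engine decides
whether a candidate actually enters the lexicon.

Rule ids:

1. syntactic inversion         ("Failure, Renal" → "Renal Failure")
2. possessives                 ("Alzheimer's disease" → "Alzheimer disease")
3. short form / long form      ("… Inhibitors (SSRIs)" → both forms)
4. angular brackets            ("Chondria <beetle>" → "Chondria")
5. semantic type               ("Surgical intervention (finding)" → "Surgical intervention")
6. begin parentheses           ("(protein) X reductase" → "X reductase")
7. begin brackets              ("[D]Respiratory abnormalities" → "Respiratory abnormalities")
8. end parentheses             ("Controls (Instrument)" → "Controls")
9. end brackets                ("Abstracts [Publication Type]" → "Abstracts")

Rules 6-9 do not apply to terms of concepts in the Chemicals & Drugs
semantic group: chemical names legitimately begin or end with brackets or
parentheses ("(S)-ibuprofen"), so stripping them would corrupt the name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "RewriteCandidate",
    "rw_syntactic_inversion",
    "rw_possessives",
    "rw_short_long_form",
    "rw_angular_brackets",
    "rw_semantic_type",
    "rw_begin_parentheses",
    "rw_begin_brackets",
    "rw_end_parentheses",
    "rw_end_brackets",
    "REWRITE_RULE_NAMES",
]

REWRITE_RULE_NAMES = {
    1: "syntactic_inversion",
    2: "possessives",
    3: "short_long_form",
    4: "angular_brackets",
    5: "semantic_type",
    6: "begin_parentheses",
    7: "begin_brackets",
    8: "end_parentheses",
    9: "end_brackets",
}

#: Rules whose output the engine flags for manual review.
REVIEW_RULES = frozenset({3, 4})

#: Rules subject to the Chemicals & Drugs exclusion.
CHEM_EXCLUDED_RULES = frozenset({6, 7, 8, 9})


@dataclass(frozen=True)
class RewriteCandidate:
    """A proposed new term string, before guard checking."""

    rule_id: int
    text: str
    source_string_id: str | None = None

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("candidate text is empty")


def _emit(rule_id: int, text: str, term: str, sid: str | None) -> list[RewriteCandidate]:
    text = text.strip()
    if not text or text == term:
        return []
    return [RewriteCandidate(rule_id=rule_id, text=text, source_string_id=sid)]


# ---------------------------------------------------------------- rule 1

def rw_syntactic_inversion(
    term: str,
    prepositions: frozenset[str] | set[str],
    string_id: str | None = None,
) -> list[RewriteCandidate]:
    """Invert "A, B" to "B A".

    Fires only when the term contains exactly one comma-space pattern and
    no token is a preposition or conjunction (which would signal a phrase
    like "Bandages, and dressings" whose inversion is not a synonym).
    """
    if term.count(", ") != 1:
        return []
    for raw_tok in term.split():
        tok = raw_tok.rstrip(".,;:!?)]}'\"").lower()
        if tok in prepositions:
            return []
    head, tail = term.split(", ", 1)
    head, tail = head.strip(), tail.strip()
    if not head or not tail:
        return []
    return _emit(1, f"{tail} {head}", term, string_id)


# ---------------------------------------------------------------- rule 2

_POSSESSIVE_RE = re.compile(r"(?<=\w)['’]s(?=\s|$)")


def rw_possessives(term: str, string_id: str | None = None) -> list[RewriteCandidate]:
    """Remove the possessive "'s" at the end of every word."""
    rewritten = _POSSESSIVE_RE.sub("", term)
    return _emit(2, rewritten, term, string_id)


# ---------------------------------------------------------------- rule 3

_MAX_SF_CHARS = 10
_MIN_SF_CHARS = 2
_MAX_SF_WORDS = 2


def _valid_short_form(sf: str) -> bool:
    if not (_MIN_SF_CHARS <= len(sf) <= _MAX_SF_CHARS):
        return False
    if len(sf.split()) > _MAX_SF_WORDS:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _find_best_long_form(sf: str, candidate: str) -> str | None:
    """Right-to-left character matching of the abbreviation pairing algorithm.

    Every alphanumeric character of the short form must appear, in order,
    in the candidate long form; the short form's first character must match
    at the start of a word.
    """
    s = len(sf) - 1
    l = len(candidate) - 1
    while s >= 0:
        c = sf[s].lower()
        if not c.isalnum():
            s -= 1
            continue
        while l >= 0 and (
            candidate[l].lower() != c
            or (s == 0 and l > 0 and candidate[l - 1].isalnum())
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    start = candidate.rfind(" ", 0, l + 1) + 1
    return candidate[start:]


def rw_short_long_form(term: str, string_id: str | None = None) -> list[RewriteCandidate]:
    """Pair a trailing parenthesized short form with its long form.

    The term is treated as a definition context "LONG FORM (SF)".  Two
    conditions restrict the pairing to dictionary entries: the short form
    must be the parenthesized expression at the very end of the term, and
    the first letters of short and long form must agree (case-insensitive).
    On success both the long form and the short form become candidates.
    """
    if not term.endswith(")"):
        return []
    open_idx = _matching_open(term, len(term) - 1, "(", ")")
    if open_idx is None or open_idx == 0:
        return []
    sf = term[open_idx + 1 : -1].strip()
    before = term[:open_idx].rstrip()
    if not before or not _valid_short_form(sf):
        return []
    # Search window: the last min(|SF|+5, |SF|*2) words before the paren.
    words = before.split()
    window = min(len(sf) + 5, len(sf) * 2)
    candidate = " ".join(words[-window:])
    lf = _find_best_long_form(sf, candidate)
    if lf is None or not lf.strip():
        return []
    lf = lf.strip()
    if len(lf) < len(sf) or lf == sf:
        return []
    if lf[0].lower() != sf[0].lower():
        return []
    out = _emit(3, lf, term, string_id) + _emit(3, sf, term, string_id)
    return out


# ---------------------------------------------------------------- rule 4

_ANGULAR_RE = re.compile(r"<[^<>]*>")
_WS_RE = re.compile(r"\s+")


def rw_angular_brackets(term: str, string_id: str | None = None) -> list[RewriteCandidate]:
    """Remove every non-nested ``<…>`` span anywhere in the term."""
    if "<" not in term:
        return []
    rewritten = _WS_RE.sub(" ", _ANGULAR_RE.sub(" ", term)).strip()
    return _emit(4, rewritten, term, string_id)


# ---------------------------------------------------------------- rule 5

def rw_semantic_type(
    term: str,
    type_names: frozenset[str] | set[str],
    string_id: str | None = None,
) -> list[RewriteCandidate]:
    """Strip a trailing parenthetical that names a semantic type.

    ``type_names`` entries must be lowercased; comparison is
    case-insensitive on the parenthetical content.
    """
    if not term.endswith(")"):
        return []
    open_idx = _matching_open(term, len(term) - 1, "(", ")")
    if open_idx is None:
        return []
    inner = term[open_idx + 1 : -1].strip()
    if inner.lower() not in type_names:
        return []
    return _emit(5, term[:open_idx].rstrip(), term, string_id)


# ------------------------------------------------------------- rules 6-9

def _matching_close(term: str, start: int, open_ch: str, close_ch: str) -> int | None:
    """Index of the close delimiter matching the opener at ``start``."""
    depth = 0
    for i in range(start, len(term)):
        if term[i] == open_ch:
            depth += 1
        elif term[i] == close_ch:
            depth -= 1
            if depth == 0:
                return i
    return None


def _matching_open(term: str, end: int, open_ch: str, close_ch: str) -> int | None:
    """Index of the open delimiter matching the closer at ``end``."""
    depth = 0
    for i in range(end, -1, -1):
        if term[i] == close_ch:
            depth += 1
        elif term[i] == open_ch:
            depth -= 1
            if depth == 0:
                return i
    return None


def _strip_begin_group(
    rule_id: int, term: str, open_ch: str, close_ch: str,
    in_chem_group: bool, sid: str | None,
) -> list[RewriteCandidate]:
    if in_chem_group or not term.startswith(open_ch):
        return []
    close_idx = _matching_close(term, 0, open_ch, close_ch)
    if close_idx is None:  # unbalanced: no candidate, not an error
        return []
    return _emit(rule_id, term[close_idx + 1 :].lstrip(), term, sid)


def _strip_end_group(
    rule_id: int, term: str, open_ch: str, close_ch: str,
    in_chem_group: bool, sid: str | None,
) -> list[RewriteCandidate]:
    if in_chem_group or not term.endswith(close_ch):
        return []
    open_idx = _matching_open(term, len(term) - 1, open_ch, close_ch)
    if open_idx is None:
        return []
    return _emit(rule_id, term[:open_idx].rstrip(), term, sid)


def rw_begin_parentheses(
    term: str, in_chem_group: bool = False, string_id: str | None = None
) -> list[RewriteCandidate]:
    """Remove a balanced parenthesized group at the beginning of the term."""
    return _strip_begin_group(6, term, "(", ")", in_chem_group, string_id)


def rw_begin_brackets(
    term: str, in_chem_group: bool = False, string_id: str | None = None
) -> list[RewriteCandidate]:
    """Remove a balanced bracketed group at the beginning of the term."""
    return _strip_begin_group(7, term, "[", "]", in_chem_group, string_id)


def rw_end_parentheses(
    term: str, in_chem_group: bool = False, string_id: str | None = None
) -> list[RewriteCandidate]:
    """Remove a balanced parenthesized group at the end of the term.

    Balanced-depth scanning (not a regex) ensures that in
    "t(3;6)(p13;q25)" only the final "(p13;q25)" group is stripped.
    """
    return _strip_end_group(8, term, "(", ")", in_chem_group, string_id)


def rw_end_brackets(
    term: str, in_chem_group: bool = False, string_id: str | None = None
) -> list[RewriteCandidate]:
    """Remove a balanced bracketed group at the end of the term."""
    return _strip_end_group(9, term, "[", "]", in_chem_group, string_id)
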