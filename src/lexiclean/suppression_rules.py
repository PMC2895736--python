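"""The eight suppression predicates.

Each predicate decides whether a term is removed from the lexicon because
it would hurt precision (e.g. the synonym "2"), is coding syntax unlikely
to occur in running text ("ADHESIVE @@ BANDAGE"), or is too long and vague
to ever be matched.  Every predicate is a pure function of the term text
(plus, where stated, a word list or the Chemicals & Drugs flag) and
returns a :class:`SuppressionVerdict` carrying the matched trigger.

Rule ids:

S1  short token        — nothing but single characters / numbers remains
S2  dosages            — number + percent/gram/microgram/milliliter unit
S3  at-sign            — contains "@"
S4  EC numbers         — IUPAC enzyme classification numbers
S5  any classification — NEC / "not elsewhere classified" / …
S6  any underspecification — NOS / "unspecified" / …
S7  miscellaneous      — leading/trailing "other", leading "unknown" …
S8  words > 5          — more than five words (not for Chemicals & Drugs)
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .normalization import (
    is_arabic_number,
    is_roman_numeral,
    remove_stopwords,
    tokenize,
    word_count,
)

__all__ = [
    "SuppressionVerdict",
    "sp_short_token",
    "sp_dosages",
    "sp_at_sign",
    "sp_ec_number",
    "sp_any_classification",
    "sp_any_underspecification",
    "sp_miscellaneous",
    "sp_words_gt5",
    "SUPPRESSION_RULE_NAMES",
]

SUPPRESSION_RULE_NAMES = {
    "S1": "short_token",
    "S2": "dosages",
    "S3": "at_sign",
    "S4": "ec_numbers",
    "S5": "any_classification",
    "S6": "any_underspecification",
    "S7": "miscellaneous",
    "S8": "words_gt5",
}

#: Suppression rules subject to the Chemicals & Drugs exclusion.
CHEM_EXCLUDED_RULES = frozenset({"S8"})


@dataclass(frozen=True)
class SuppressionVerdict:
    rule_id: str
    suppressed: bool
    trigger: str = ""
    string_id: str | None = None

    def __post_init__(self):
        if self.suppressed and not self.trigger:
            raise ValueError("a suppressing verdict must name its trigger")

    def __bool__(self) -> bool:
        return self.suppressed


def _kept(rule_id: str, sid: str | None) -> SuppressionVerdict:
    return SuppressionVerdict(rule_id=rule_id, suppressed=False, string_id=sid)


def _supp(rule_id: str, trigger: str, sid: str | None) -> SuppressionVerdict:
    return SuppressionVerdict(rule_id=rule_id, suppressed=True, trigger=trigger, string_id=sid)


# ------------------------------------------------------------------ S1

def sp_short_token(
    term: str,
    stoplist: frozenset[str] | set[str],
    string_id: str | None = None,
) -> SuppressionVerdict:
    """Suppress terms with no content-bearing token.

    After tokenization and stop-word removal, each remaining token is
    examined separately; the term is suppressed when nothing remains or
    when every remaining token is a single character, an arabic number, or
    a roman numeral ("10*9/L" tokenizes to "10 9 l" and is suppressed).
    """
    remaining = remove_stopwords(tokenize(term), stoplist)
    if len(remaining) == 0:
        return _supp("S1", "<no tokens after stop-word removal>", string_id)
    if all(
        len(t.text) == 1 or is_arabic_number(t.text) or is_roman_numeral(t.text)
        for t in remaining
    ):
        return _supp("S1", remaining.joined(), string_id)
    return _kept("S1", string_id)


# ------------------------------------------------------------------ S2

def _dosage_pattern(units: frozenset[str] | set[str]) -> re.Pattern:
    alts = "|".join(sorted((re.escape(u) for u in units), key=len, reverse=True))
    return re.compile(
        rf"(?<![A-Za-z0-9.])\d+(?:\.\d+)? ?(?:{alts})(?![A-Za-z])",
        re.IGNORECASE,
    )


_DEFAULT_UNITS_PATTERN: dict[frozenset, re.Pattern] = {}


def sp_dosages(
    term: str,
    units: frozenset[str] | set[str] | None = None,
    string_id: str | None = None,
) -> SuppressionVerdict:
    """Suppress terms containing a dosage: a number immediately followed
    (optionally after one space) by a percent/gram/microgram/milliliter
    unit token.  "Vitamin B12" is kept: the digits are glued to a letter.
    """
    from .resources import DEFAULT_UNITS

    units = frozenset(units) if units is not None else DEFAULT_UNITS
    pat = _DEFAULT_UNITS_PATTERN.get(units)
    if pat is None:
        pat = _dosage_pattern(units)
        _DEFAULT_UNITS_PATTERN[units] = pat
    m = pat.search(term)
    if m:
        return _supp("S2", m.group(0), string_id)
    return _kept("S2", string_id)


# ------------------------------------------------------------------ S3

def sp_at_sign(term: str, string_id: str | None = None) -> SuppressionVerdict:
    """Suppress terms containing the @-character anywhere."""
    if "@" in term:
        return _supp("S3", "@", string_id)
    return _kept("S3", string_id)


# ------------------------------------------------------------------ S4

_EC_RE = re.compile(r"(?<![A-Za-z0-9])EC ?\d+(?:\.(?:\d+|-)){1,3}")


def sp_ec_number(term: str, string_id: str | None = None) -> SuppressionVerdict:
    """Suppress terms containing IUPAC enzyme classification numbers.

    Matches "EC" (case-sensitive, at a word boundary) followed by an
    optional space and 2-4 dot-separated fields of digits or "-"
    ("EC 2.7.1.112", "EC 2.7.1.-").
    """
    m = _EC_RE.search(term)
    if m:
        return _supp("S4", m.group(0), string_id)
    return _kept("S4", string_id)


# --------------------------------------------------------------- S5, S6

def _positional_code(term: str, code: str) -> str | None:
    """Terminal ",  CODE" or " (CODE)" / " [CODE]" patterns (case-sensitive)."""
    stripped = term.rstrip()
    if re.search(rf",\s*{code}$", stripped):
        return f", {code}"
    for open_ch, close_ch in ("()", "[]"):
        suffix = f"{open_ch}{code}{close_ch}"
        if stripped.endswith(suffix):
            before = stripped[: -len(suffix)]
            if before.endswith(" "):
                return f" {suffix}"
    return None


def _substring_or_code(
    rule_id: str, term: str, substrings: tuple[str, ...], code: str,
    sid: str | None,
) -> SuppressionVerdict:
    low = term.lower()
    for s in substrings:
        if s in low:
            return _supp(rule_id, s, sid)
    trig = _positional_code(term, code)
    if trig is not None:
        return _supp(rule_id, trig, sid)
    return _kept(rule_id, sid)


def sp_any_classification(term: str, string_id: str | None = None) -> SuppressionVerdict:
    """Suppress classification-rubric terms.

    Case-insensitive substrings "not elsewhere classified", "unclassified",
    "without mention" anywhere; "NEC" (uppercase) at the end preceded by a
    comma, or "(NEC)"/"[NEC]" at the end preceded by a space.
    """
    return _substring_or_code(
        "S5", term,
        ("not elsewhere classified", "unclassified", "without mention"),
        "NEC", string_id,
    )


def sp_any_underspecification(term: str, string_id: str | None = None) -> SuppressionVerdict:
    """Suppress underspecified rubric terms ("… , NOS", "unspecified" …)."""
    return _substring_or_code(
        "S6", term,
        ("not otherwise specified", "not specified", "unspecified"),
        "NOS", string_id,
    )


# ------------------------------------------------------------------ S7

_MISC_BEGIN = ("other", "deprecated", "unknown", "obsolete", "miscellaneous", "no")
#: Bare "no"/"NO" is left to the short-token rule's single-token path.
_MISC_EXACT = frozenset({"other", "deprecated", "unknown", "obsolete", "miscellaneous"})


def sp_miscellaneous(term: str, string_id: str | None = None) -> SuppressionVerdict:
    """Suppress residual-category terms.

    Case-insensitive: "other" at the beginning followed by a space or at
    the end preceded by a space; "deprecated", "unknown", "obsolete",
    "miscellaneous" or "no" at the beginning followed by a space; or the
    whole term equal to one of the keywords (e.g. the bare term "Other").
    """
    low = term.lower()
    if low in _MISC_EXACT:
        return _supp("S7", term, string_id)
    if low.endswith(" other"):
        return _supp("S7", " other", string_id)
    for kw in _MISC_BEGIN:
        if low.startswith(kw + " "):
            return _supp("S7", kw + " ", string_id)
    return _kept("S7", string_id)


# ------------------------------------------------------------------ S8

def sp_words_gt5(
    term: str,
    in_chem_group: bool = False,
    string_id: str | None = None,
) -> SuppressionVerdict:
    """Suppress terms of more than five raw whitespace-separated words.

    Not applied to Chemicals & Drugs concepts, whose systematic names are
    legitimately long.
    """
    if in_chem_group:
        return _kept("S8", string_id)
    n = word_count(term)
    if n > 5:
        return _supp("S8", f"{n} words", string_id)
    return _kept("S8", string_id)
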