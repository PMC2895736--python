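"""Shared text normalization for deduplication, rewriting, and matching.

Every component that compares term strings — within-concept deduplication,
the duplicate/homonym guard, and the corpus recognizer — goes through the
single normal form implemented here: lowercase, punctuation replaced by
spaces, whitespace collapsed.  Keeping one normal form guarantees that a
string judged a duplicate at curation time is also the string the matcher
would find, and vice versa.

Punctuation is *replaced by a space*, never deleted: "10*9/L" must become
the three tokens "10", "9", "l" (a term made only of numbers and single
characters, which the short-token suppression rule removes).  The
punctuation class is Unicode punctuation plus the symbol characters
``* / @ + = < >``; letters and digits are never punctuation.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "TokenSequence",
    "normalize_key",
    "tokenize",
    "remove_stopwords",
    "is_roman_numeral",
    "is_arabic_number",
    "word_count",
]

# Symbols treated as separators in addition to Unicode punctuation (category P*).
_EXTRA_PUNCT = frozenset("*/@+=<>")


def _is_punct(ch: str) -> bool:
    if ch.isalnum():
        return False
    if ch in _EXTRA_PUNCT:
        return True
    return unicodedata.category(ch).startswith("P")


@dataclass(frozen=True)
class Token:
    """One lowercased token with its character span in the original text."""

    text: str
    start: int
    end: int  # half-open


class TokenSequence:
    """Ordered tokens with non-overlapping, monotonically increasing spans."""

    __slots__ = ("tokens",)

    def __init__(self, tokens: Iterable[Token]):
        self.tokens: tuple[Token, ...] = tuple(tokens)

    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def joined(self) -> str:
        return " ".join(t.text for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, TokenSequence):
            return self.tokens == other.tokens
        return NotImplemented

    def __repr__(self) -> str:
        return f"TokenSequence({list(self.texts())!r})"


def tokenize(text: str) -> TokenSequence:
    """Split *text* into lowercased tokens at whitespace and punctuation.

    Tokens are maximal runs of characters that are neither whitespace nor
    punctuation; each carries its character offsets into the original text.
    """
    tokens: list[Token] = []
    start: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace() or _is_punct(ch):
            if start is not None:
                tokens.append(Token(text[start:i].lower(), start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        tokens.append(Token(text[start:].lower(), start, len(text)))
    return TokenSequence(tokens)


def normalize_key(text: str) -> str:
    """Normal form used for dedup, the guard, and the matcher index.

    Lowercase; every punctuation character becomes a space; runs of
    whitespace collapse to single spaces; leading/trailing space trimmed.
    May return the empty string (e.g. for "@@").
    """
    return tokenize(text).joined()


def remove_stopwords(tokens: TokenSequence, stoplist: frozenset[str] | set[str]) -> TokenSequence:
    """Drop tokens found in *stoplist* (entries must be lowercase)."""
    return TokenSequence(t for t in tokens if t.text not in stoplist)


_ROMAN_RE = re.compile(r"m{0,3}(cm|cd|d?c{0,3})(xc|xl|l?x{0,3})(ix|iv|v?i{0,3})")


def is_roman_numeral(token: str) -> bool:
    """True iff *token* (lowercase) is a well-formed roman numeral 1-3999."""
    return bool(token) and _ROMAN_RE.fullmatch(token) is not None


_ARABIC_RE = re.compile(r"\d+(\.\d+)?")


def is_arabic_number(token: str) -> bool:
    """True iff *token* is all digits, or digits with one decimal point."""
    return bool(_ARABIC_RE.fullmatch(token))


def word_count(text: str) -> int:
    """Number of whitespace-separated units of the *raw* text.

    Hyphenated compounds count as one word: "insulin-like growth factor
    binding protein 1" has six words, not seven.
    """
    return len(text.split())
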