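"""Loading of vendored and user-supplied resource lists.

All list-style resources share one plain-text format: one entry per line,
"#" starts a comment line, blank lines ignored.  The vendored defaults can
be replaced per rule configuration with any file in the same format.
"""

from __future__ import annotations

from importlib import resources as _ilr
from pathlib import Path

_DATA = _ilr.files("lexiclean") / "data"

DEFAULT_STOPWORDS = "pubmed_stopwords.txt"
DEFAULT_SEMANTIC_TYPES = "semantic_types.txt"
DEFAULT_PREPOSITIONS = "prepositions.txt"
DEFAULT_SEMANTIC_GROUPS = "semantic_groups.txt"

#: Default dosage unit tokens: percent, gram, microgram, milliliter families.
DEFAULT_UNITS = frozenset(
    {
        "%",
        "percent",
        "g",
        "gm",
        "gram",
        "grams",
        "mcg",
        "ug",
        "µg",  # µg
        "microgram",
        "micrograms",
        "ml",
        "milliliter",
        "milliliters",
    }
)

CHEMICALS_AND_DRUGS = "Chemicals & Drugs"


def _parse_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line)
    return out


def load_wordlist(path: str | Path | None, default: str, *, lower: bool = True) -> frozenset[str]:
    """Load a word list from *path*, or the vendored *default* when None."""
    if path is None:
        text = (_DATA / default).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = _parse_lines(text)
    if lower:
        words = [w.lower() for w in words]
    return frozenset(words)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    return load_wordlist(path, DEFAULT_STOPWORDS)


def load_prepositions(path: str | Path | None = None) -> frozenset[str]:
    return load_wordlist(path, DEFAULT_PREPOSITIONS)


def load_semantic_type_names(path: str | Path | None = None) -> frozenset[str]:
    """Semantic-type names, lowercased for case-insensitive comparison."""
    return load_wordlist(path, DEFAULT_SEMANTIC_TYPES)


def default_semantic_groups_path() -> Path:
    """Path of the vendored type→group mapping (SemGroups dialect)."""
    return Path(str(_DATA / DEFAULT_SEMANTIC_GROUPS))
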