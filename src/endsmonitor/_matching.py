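"""Shared longest-match-first phrase matcher.

Both the keyword filter and the gazetteer entity extractor need the same
contract: case-insensitive, non-overlapping matches over a text, preferring
the longest term at each position, with optional token-boundary checking
(disabled for unsegmented scripts such as Chinese).
"""

from __future__ import annotations

import re
import unicodedata
from typing import NamedTuple, Sequence


class Match(NamedTuple):
    term: str        # canonical (normalized) form of the matched entry
    start: int       # 0-based character offset into the searched text
    end: int         # half-open


def normalize_term(term: str) -> str:
    """Lowercase, fold non-breaking spaces/hyphen runs, collapse whitespace."""
    term = unicodedata.normalize("NFKC", term).lower()
    term = re.sub(r"\s+", " ", term).strip()
    return term


def canonical_key(term: str) -> str:
    """Normalization for table lookup: spaces and hyphens collapse together."""
    return re.sub(r"[\s-]+", " ", normalize_term(term)).strip()


def compile_matcher(terms: Sequence[str], boundaries: bool = True) -> re.Pattern:
    """Compile an alternation over normalized terms.

    Longest-first ordering in the alternation gives longest-match-at-position
    semantics; the regex scanner then yields non-overlapping matches left to
    right. A space in a listed term matches any whitespace or hyphen run and a
    hyphen matches a hyphen or whitespace, so "e cig" / "e-cig" surface
    variants interchange.
    """
    normalized = sorted({normalize_term(t) for t in terms if normalize_term(t)},
                        key=len, reverse=True)
    if not normalized:
        raise ValueError("no non-empty terms to compile")
    parts = []
    for term in normalized:
        esc = re.escape(term)
        esc = esc.replace("\\ ", "[\\s-]+").replace("\\-", "[\\s-]")
        parts.append(esc)
    body = "|".join(parts)
    if boundaries:
        pattern = rf"(?<!\w)(?:{body})(?!\w)"
    else:
        pattern = f"(?:{body})"
    return re.compile(pattern, re.IGNORECASE | re.UNICODE)


def find_matches(text: str, pattern: re.Pattern) -> list[Match]:
    """All non-overlapping matches, canonicalized via normalize_term."""
    return [Match(term=normalize_term(m.group(0)), start=m.start(), end=m.end())
            for m in pattern.finditer(text)]
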