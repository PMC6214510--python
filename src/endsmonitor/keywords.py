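"""Keyword selection stage: keep articles mentioning at least one ENDS term.

The bundled English table carries the canonical ENDS vocabulary — the
"electronic cigarette(s) / e(-)cig(arette)(s) / vape(r)(s) / vaping" family —
with singulars and plurals expanded. Tables for other languages are editable
data files; bundled non-English entries are illustrative placeholders, not
authoritative translations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from ._matching import compile_matcher, find_matches, normalize_term
from .corpus import NewsArticle

logger = logging.getLogger(__name__)

#: Languages written without whitespace word segmentation; boundary checking
#: is meaningless there, so pure substring matching is used.
UNSEGMENTED_LANGUAGES = frozenset({"zh", "ja", "th", "km", "lo", "my"})

#: Canonical English ENDS terms, singulars and plurals expanded.
ENGLISH_TERMS = (
    "electronic cigarette", "electronic cigarettes",
    "e cig", "e cigs",
    "e-cig", "e-cigs",
    "ecig", "ecigs",
    "e cigarette", "e cigarettes",
    "e-cigarette", "e-cigarettes",
    "ecigarette", "ecigarettes",
    "vape", "vapes",
    "vaper", "vapers",
    "vaping",
)


@dataclass(frozen=True)
class MentionSpan:
    """One keyword occurrence: term, character span, and which field it hit."""

    term: str
    start: int
    end: int
    field: str  # "title" or "body"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.field not in ("title", "body"):
            raise ValueError(f"field must be 'title' or 'body', got {self.field!r}")


@dataclass
class KeywordTable:
    """Per-language ENDS term lists with compiled matchers."""

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)
    case_sensitive: bool = False  # matching is case-insensitive per contract
    _patterns: dict[str, re.Pattern] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        cleaned = {}
        for lang, terms in self.entries.items():
            terms = tuple(t for t in (normalize_term(x) for x in terms) if t)
            if not terms:
                raise ValueError(f"language {lang!r} has no non-empty terms")
            cleaned[lang] = terms
        self.entries = cleaned

    def pattern_for(self, language: str) -> re.Pattern:
        lang = language.split("-")[0].lower()
        if lang not in self.entries:
            logger.warning("no keyword table for language %r; falling back to English", language)
            lang = "en"
        if lang not in self._patterns:
            self._patterns[lang] = compile_matcher(
                self.entries[lang], boundaries=lang not in UNSEGMENTED_LANGUAGES
            )
        return self._patterns[lang]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "KeywordTable":
        """Load a tab-separated table with columns ``language``, ``term``."""
        entries: dict[str, list[str]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                lang, term = line.split("\t", 1)
                if lang == "language":  # header
                    continue
                entries.setdefault(lang, []).append(term)
        return cls(entries={k: tuple(v) for k, v in entries.items()})

    @classmethod
    def bundled(cls) -> "KeywordTable":
        """The table shipped with the package (English list is canonical)."""
        ref = resources.files("endsmonitor.data") / "keywords.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def match_keywords(
    title: str, body: str, table: KeywordTable, language: str = "en"
) -> list[MentionSpan]:
    """All non-overlapping keyword matches in title and body.

    Longest match wins at each position; matching is case-insensitive and
    token-boundary-delimited for space-segmented languages.
    """
    pattern = table.pattern_for(language)
    spans = [MentionSpan(m.term, m.start, m.end, "title")
             for m in find_matches(title, pattern)]
    spans += [MentionSpan(m.term, m.start, m.end, "body")
              for m in find_matches(body, pattern)]
    return spans


def filter_corpus(
    articles: Sequence[NewsArticle], table: Optional[KeywordTable] = None
) -> tuple[list[NewsArticle], dict[str, list[MentionSpan]]]:
    """Keep exactly the articles with >= 1 keyword mention in title or body.

    Returns the retained articles (input order) and a per-article-id map of
    their mention spans for downstream feature extraction.
    """
    if table is None:
        table = KeywordTable.bundled()
    kept: list[NewsArticle] = []
    spans_by_id: dict[str, list[MentionSpan]] = {}
    for art in articles:
        spans = match_keywords(art.title, art.body, table, art.language)
        if spans:
            kept.append(art)
            spans_by_id[art.id] = spans
    return kept, spans_by_id
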