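"""Geographic-focus resolution.

The focal nation of an article — the one it is *about*, not where it was
published — is resolved from the distribution of gazetteer entities
(place names and country-linked organizations) in the text:

* no entities                         -> "UNK"
* one country holds a strict majority -> that country's ISO 3166 alpha-3 code
* every country at 50% or fewer       -> "MUL" (multinational)
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from ._matching import canonical_key, compile_matcher, find_matches

MULTINATIONAL = "MUL"
UNKNOWN = "UNK"

_ALPHA3 = re.compile(r"^[A-Z]{3}$")


@dataclass
class Gazetteer:
    """Surface form -> ISO 3166 alpha-3 lookup with a compiled matcher."""

    surface_forms: dict[str, str]  # canonical_key(surface) -> alpha-3
    _pattern: Optional[re.Pattern] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for surface, code in self.surface_forms.items():
            key = canonical_key(surface)
            if not _ALPHA3.match(code):
                raise ValueError(f"invalid alpha-3 code {code!r} for {surface!r}")
            if key in cleaned and cleaned[key] != code:
                # homonyms: first entry wins (documented behavior)
                continue
            cleaned[key] = code
        self.surface_forms = cleaned

    @property
    def pattern(self) -> re.Pattern:
        if self._pattern is None:
            self._pattern = compile_matcher(list(self.surface_forms), boundaries=True)
        return self._pattern

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "Gazetteer":
        """Load a tab-separated file with columns ``surface_form``, ``iso3``."""
        forms: dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                surface, code = line.split("\t", 1)
                if surface == "surface_form":
                    continue
                key = canonical_key(surface)
                if key not in forms:  # first entry wins
                    forms[key] = code.strip()
        return cls(surface_forms=forms)

    @classmethod
    def bundled(cls) -> "Gazetteer":
        ref = resources.files("endsmonitor.data") / "gazetteer.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class GeoMentionCounts:
    """Per-country entity tallies for one article."""

    counts: Mapping[str, int]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "GeoMentionCounts":
        counts = {k: int(v) for k, v in counts.items() if v > 0}
        return cls(counts=counts, total=sum(counts.values()))


def extract_entities(title: str, body: str, gazetteer: Gazetteer) -> GeoMentionCounts:
    """Tally gazetteer hits over title + body.

    Case-insensitive, longest-match-first, non-overlapping; each match
    increments its country's tally by one.
    """
    tally: Counter[str] = Counter()
    for text in (title, body):
        for m in find_matches(text, gazetteer.pattern):
            code = gazetteer.surface_forms.get(canonical_key(m.term))
            if code is not None:
                tally[code] += 1
    return GeoMentionCounts.from_counts(tally)


def resolve_geo_focus(counts: GeoMentionCounts) -> str:
    """Apply the one-entity / strict-majority / multinational rule."""
    if counts.total == 0:
        return UNKNOWN
    best_code, best_n = max(counts.counts.items(), key=lambda kv: (kv[1], kv[0]))
    if 2 * best_n > counts.total:  # strictly more than 50% of mentions
        return best_code
    return MULTINATIONAL


def geo_distribution(
    labels: Sequence[str], top_k: Optional[int] = None, include_unknown: bool = False
) -> list[tuple[str, float]]:
    """Ranked (label, percentage) list over the labeled articles.

    Percentages are over all included articles (multinational always counted;
    unknown excluded unless ``include_unknown``). Ties break alphabetically.
    """
    if not labels:
        raise ValueError("empty label sequence")
    pool = [l for l in labels if include_unknown or l != UNKNOWN]
    if not pool:
        return []
    tally = Counter(pool)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    out = [(label, 100.0 * n / len(pool)) for label, n in ranked]
    return out[:top_k] if top_k is not None else out
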