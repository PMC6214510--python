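"""Lexicon sentiment scoring on a -1..1 scale.

Each article is split into sentences; each sentence gets a bag-of-words
polarity score (P - N)/(P + N) over matched lexicon weights; the article
score is the mean of its sentence scores (sentences with no lexicon words
count as 0, which keeps long factual articles near neutral). Categories
follow the +-0.5 "strongly" convention by default; a narrower band set
(+-0.05 strongly, +-0.01 non-neutral) ships as a named alternative.

The scorer is deliberately transparent and deterministic; an external
sentence scorer can be plugged in through the ``sentence_scorer`` hook of
:func:`score_article`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

CATEGORIES = (
    "strongly_negative", "somewhat_negative", "neutral",
    "somewhat_positive", "strongly_positive",
)

#: (strong threshold, neutral half-width). Default follows the +-0.5
#: "strongly" convention; "narrow" mirrors the +-0.05 / +-0.01 convention.
BAND_PRESETS = {
    "default": (0.5, 0.01),
    "narrow": (0.05, 0.01),
}

#: Abbreviations whose trailing period does not end a sentence.
_ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "sr", "jr", "st", "no", "vs",
    "e.g", "i.e", "etc", "u.s", "u.k", "fig", "inc", "ltd", "co",
})

_SENTENCE_END = re.compile(r"([.!?]+)(\s+|$)")
_TOKEN = re.compile(r"[\w']+")


@dataclass(frozen=True)
class SentimentLexicon:
    """Token -> polarity weight in [-1, 1], tokens lowercased and unique."""

    polarities: dict[str, float]

    def __post_init__(self) -> None:
        for tok, w in self.polarities.items():
            if tok != tok.lower():
                raise ValueError(f"lexicon token {tok!r} must be lowercase")
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"weight for {tok!r} out of [-1, 1]: {w}")

    def flipped(self) -> "SentimentLexicon":
        return SentimentLexicon({t: -w for t, w in self.polarities.items()})

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SentimentLexicon":
        pol: dict[str, float] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                tok, w = line.split("\t", 1)
                if tok == "token":
                    continue
                pol[tok.lower()] = float(w)
        return cls(polarities=pol)

    @classmethod
    def bundled(cls) -> "SentimentLexicon":
        ref = resources.files("endsmonitor.data") / "lexicon.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class SentimentResult:
    score: float
    sentence_scores: tuple[float, ...]
    category: str


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation followed by whitespace or end of text.

    Periods after known abbreviations do not split; empty segments drop.
    """
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        candidate = text[start:m.end(1)]
        last_word = re.findall(r"[\w.]+(?=[.!?]+$)", candidate.strip())
        if m.group(1) == "." and last_word and last_word[-1].lower() in _ABBREVIATIONS:
            continue
        if candidate.strip():
            sentences.append(candidate.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def score_sentence(sentence: str, lexicon: SentimentLexicon) -> float:
    """(P - N) / (P + N) over matched lexicon weights; 0 when nothing matches."""
    pos = 0.0
    neg = 0.0
    for tok in _TOKEN.findall(sentence.lower()):
        w = lexicon.polarities.get(tok)
        if w is None:
            continue
        if w > 0:
            pos += w
        else:
            neg += -w
    total = pos + neg
    return (pos - neg) / total if total > 0 else 0.0


def categorize_sentiment(
    score: float, strong: float = 0.5, neutral_band: float = 0.01
) -> str:
    """Map a score in [-1, 1] to a five-way sentiment category."""
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score out of [-1, 1]: {score}")
    if score <= -strong:
        return "strongly_negative"
    if score >= strong:
        return "strongly_positive"
    if abs(score) < neutral_band:
        return "neutral"
    return "somewhat_negative" if score < 0 else "somewhat_positive"


def score_article(
    title: str,
    body: str,
    lexicon: Optional[SentimentLexicon] = None,
    strong: float = 0.5,
    neutral_band: float = 0.01,
    aggregate: str = "mean",
    sentence_scorer: Optional[Callable[[str], float]] = None,
) -> SentimentResult:
    """Score one article: sentences from title + body, aggregated score,
    category from the band thresholds.

    ``aggregate`` is "mean" (default) or "median". A custom
    ``sentence_scorer`` replaces the lexicon scorer when provided.
    """
    if lexicon is None and sentence_scorer is None:
        lexicon = SentimentLexicon.bundled()
    scorer = sentence_scorer or (lambda s: score_sentence(s, lexicon))
    sentences = split_sentences(title) + split_sentences(body)
    sentence_scores = tuple(float(scorer(s)) for s in sentences)
    if not sentence_scores:
        score = 0.0
    elif aggregate == "mean":
        score = sum(sentence_scores) / len(sentence_scores)
    elif aggregate == "median":
        srt = sorted(sentence_scores)
        mid = len(srt) // 2
        score = srt[mid] if len(srt) % 2 else (srt[mid - 1] + srt[mid]) / 2.0
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return SentimentResult(
        score=score,
        sentence_scores=sentence_scores,
        category=categorize_sentiment(score, strong=strong, neutral_band=neutral_band),
    )


def corpus_sentiment_summary(
    results: Sequence[SentimentResult],
) -> dict[str, float]:
    """Mean, sample SD, and category shares (percent) over scored articles."""
    if not results:
        raise ValueError("empty results")
    import numpy as np

    scores = np.array([r.score for r in results])
    summary: dict[str, float] = {
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
    }
    n = len(results)
    for cat in CATEGORIES:
        summary[f"pct_{cat}"] = 100.0 * sum(r.category == cat for r in results) / n
    return summary
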