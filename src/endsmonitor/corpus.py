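"""Core record types and corpus readers/writers.

A corpus is a UTF-8 JSON-lines file, one news article per line, with a fixed
field order. Ground-truth labels (used for training and evaluation) live in a
sidecar file of the same convention keyed by ``article_id``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

logger = logging.getLogger(__name__)

#: JSON field order for serialized articles (deterministic output).
ARTICLE_FIELDS = (
    "id",
    "url",
    "source",
    "published_at",
    "language",
    "title",
    "body",
    "pagerank",
    "twitter_shares",
    "facebook_shares",
)


class CorpusFormatError(ValueError):
    """A corpus line violates the documented schema."""


@dataclass(frozen=True)
class NewsArticle:
    """One news report with text, timestamp, and raw popularity signals.

    ``published_at`` is a UTC calendar date (sub-day precision from the input
    is normalized away on read; the analytics aggregate by day). ``pagerank``
    follows the conventional 0-10 scale and is consumed as an external input
    signal, never computed here.
    """

    id: str
    url: str
    source: str
    published_at: _dt.date
    language: str
    title: str
    body: str
    pagerank: float = 0.0
    twitter_shares: int = 0
    facebook_shares: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("article id must be non-empty")
        if self.pagerank < 0:
            raise ValueError(f"pagerank must be >= 0, got {self.pagerank}")
        for field in ("twitter_shares", "facebook_shares"):
            v = getattr(self, field)
            if v < 0 or int(v) != v:
                raise ValueError(f"{field} must be a nonnegative integer, got {v!r}")

    @property
    def total_shares(self) -> int:
        return self.twitter_shares + self.facebook_shares


@dataclass(frozen=True)
class LabeledArticle:
    """Ground-truth sidecar record for one article.

    Any subset of the truth fields may be present; absent truths are ``None``.
    """

    article_id: str
    focus_truth: Optional[bool] = None
    geo_truth: Optional[str] = None
    subject_truth: Optional[str] = None
    sentiment_truth: Optional[float] = None


def _parse_date(value: str) -> _dt.date:
    """Parse an ISO date or timestamp to a UTC calendar date."""
    try:
        ts = _dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError as exc:
        raise CorpusFormatError(f"unparseable timestamp {value!r}") from exc
    if ts.tzinfo is not None:
        ts = ts.astimezone(_dt.timezone.utc)
    return ts.date()


def _article_from_record(rec: dict) -> NewsArticle:
    required = ("id", "url", "source", "published_at", "language", "title", "body")
    missing = [f for f in required if f not in rec]
    if missing:
        raise CorpusFormatError(f"missing required field(s): {', '.join(missing)}")
    for f in ("pagerank", "twitter_shares", "facebook_shares"):
        if f not in rec or rec[f] is None:
            logger.warning("article %s missing %s; defaulting to 0", rec["id"], f)
            rec[f] = 0
    return NewsArticle(
        id=str(rec["id"]),
        url=str(rec["url"]),
        source=str(rec["source"]),
        published_at=_parse_date(str(rec["published_at"])),
        language=str(rec["language"]),
        title=str(rec["title"]),
        body=str(rec["body"]),
        pagerank=float(rec["pagerank"]),
        twitter_shares=int(rec["twitter_shares"]),
        facebook_shares=int(rec["facebook_shares"]),
    )


def read_corpus(
    path: Union[str, Path], strict: bool = True
) -> tuple[list[NewsArticle], int]:
    """Read a JSON-lines corpus.

    Returns ``(articles, skipped_count)``. In strict mode any malformed line
    raises :class:`CorpusFormatError`; in lenient mode malformed lines are
    counted, logged, and skipped. Blank lines are ignored in both modes.
    """
    path = Path(path)
    articles: list[NewsArticle] = []
    seen_ids: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                if not isinstance(rec, dict):
                    raise CorpusFormatError("line is not a JSON object")
                art = _article_from_record(rec)
                if art.id in seen_ids:
                    raise CorpusFormatError(f"duplicate article id {art.id!r}")
            except (json.JSONDecodeError, CorpusFormatError, ValueError) as exc:
                if strict:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
                skipped += 1
                continue
            seen_ids.add(art.id)
            articles.append(art)
    return articles, skipped


def write_corpus(articles: Iterable[NewsArticle], path: Union[str, Path]) -> int:
    """Write articles as JSON lines with deterministic field order.

    Returns the record count.
    """
    path = Path(path)
    count = 0
    with path.open("w", encoding="utf-8") as fh:
        for art in articles:
            rec = {
                f: (art.published_at.isoformat() if f == "published_at" else getattr(art, f))
                for f in ARTICLE_FIELDS
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            count += 1
    return count


def read_labels(path: Union[str, Path]) -> list[LabeledArticle]:
    """Read the ground-truth sidecar (JSON lines keyed by article_id)."""
    labels = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            labels.append(
                LabeledArticle(
                    article_id=str(rec["article_id"]),
                    focus_truth=rec.get("focus_truth"),
                    geo_truth=rec.get("geo_truth"),
                    subject_truth=rec.get("subject_truth"),
                    sentiment_truth=rec.get("sentiment_truth"),
                )
            )
    return labels


def write_labels(labels: Iterable[LabeledArticle], path: Union[str, Path]) -> int:
    count = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for lab in labels:
            rec = {k: v for k, v in dataclasses.asdict(lab).items() if v is not None or k == "article_id"}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            count += 1
    return count


def check_labels_resolve(
    labels: Sequence[LabeledArticle], articles: Sequence[NewsArticle]
) -> None:
    """Raise if any labeled id does not resolve to a corpus article."""
    ids = {a.id for a in articles}
    dangling = [l.article_id for l in labels if l.article_id not in ids]
    if dangling:
        raise ValueError(f"{len(dangling)} label(s) reference unknown article ids, e.g. {dangling[0]!r}")
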