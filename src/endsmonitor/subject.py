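"""Subject-focus classification over the 9 tobacco-policy categories.

The taxonomy is motivated by the WHO MPOWER policy package: prevalence,
bans, quitting, warnings, marketing, prices, age, flavor, industry — plus
"other" for articles fitting none of them. "other" arises two ways:
two annotators disagreeing at adjudication, or the classifier finding no
category with enough evidence (a probability margin).

The reference learner is one-vs-rest logistic regression on bag-of-words
term frequencies; the model surface (vocabulary + per-category weight
vectors) is plain data so alternative learners can be plugged in.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import NewsArticle

logger = logging.getLogger(__name__)

SUBJECT_CATEGORIES = (
    "age", "bans", "flavor", "industry", "marketing",
    "prevalence", "prices", "quitting", "warnings",
)
OTHER = "other"
ALL_LABELS = SUBJECT_CATEGORIES + (OTHER,)

#: Below this top one-vs-rest probability the classifier abstains to "other".
DEFAULT_MARGIN = 0.5


def validate_label(label: str) -> str:
    if label not in ALL_LABELS:
        raise ValueError(f"unknown subject label {label!r}; admissible: {ALL_LABELS}")
    return label


def adjudicate_labels(a: str, b: str) -> str:
    """Collapse two annotators' labels: agreement stands, disagreement -> other."""
    validate_label(a)
    validate_label(b)
    return a if a == b else OTHER


@dataclass
class SubjectModel:
    """Vocabulary and per-category linear weights, plus training metadata."""

    vocabulary: dict[str, int]
    intercepts: dict[str, float]
    weights: dict[str, np.ndarray]  # category -> weight vector over vocabulary
    margin: float = DEFAULT_MARGIN
    n_training_examples: int = 0
    seed: int = 0

    def save(self, path: Union[str, Path]) -> None:
        blob = {
            "vocabulary": self.vocabulary,
            "intercepts": self.intercepts,
            "weights": {k: v.tolist() for k, v in self.weights.items()},
            "margin": self.margin,
            "n_training_examples": self.n_training_examples,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(blob), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SubjectModel":
        blob = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            vocabulary=blob["vocabulary"],
            intercepts=blob["intercepts"],
            weights={k: np.asarray(v) for k, v in blob["weights"].items()},
            margin=blob["margin"],
            n_training_examples=blob["n_training_examples"],
            seed=blob["seed"],
        )


def _vectorizer(vocabulary: Optional[dict[str, int]] = None) -> CountVectorizer:
    # lowercased, punctuation-stripped word tokens; raw term frequency
    return CountVectorizer(lowercase=True, token_pattern=r"(?u)\b\w\w+\b",
                           vocabulary=vocabulary)


def train_subject_classifier(
    articles: Sequence[NewsArticle],
    labels: Sequence[str],
    seed: int = 0,
    margin: float = DEFAULT_MARGIN,
    min_per_category: int = 10,
) -> SubjectModel:
    """Fit one-vs-rest logistic classifiers on bag-of-words counts.

    Requires every one of the 9 substantive categories at least
    ``min_per_category`` times in the (adjudicated) labels. "other"-labeled
    articles act as negatives for every category. Deterministic given seed.
    """
    if len(articles) != len(labels):
        raise ValueError("articles and labels length mismatch")
    for lab in labels:
        validate_label(lab)
    tally = Counter(labels)
    missing = [c for c in SUBJECT_CATEGORIES if tally[c] < min_per_category]
    if missing:
        raise ValueError(
            f"categories below {min_per_category} training examples: {missing}"
        )
    texts = [f"{a.title} {a.body}" for a in articles]
    if any(not t.strip() for t in texts):
        raise ValueError("empty documents in training data")
    vec = _vectorizer()
    X = vec.fit_transform(texts)
    y = np.asarray(labels)
    rng_seed = int(seed) % (2**31)
    intercepts: dict[str, float] = {}
    weights: dict[str, np.ndarray] = {}
    for cat in SUBJECT_CATEGORIES:
        clf = LogisticRegression(solver="lbfgs", max_iter=5_000, tol=1e-6,
                                 random_state=rng_seed)
        clf.fit(X, (y == cat).astype(int))
        intercepts[cat] = float(clf.intercept_[0])
        weights[cat] = clf.coef_.ravel().copy()
    return SubjectModel(
        vocabulary={t: int(i) for t, i in vec.vocabulary_.items()},
        intercepts=intercepts,
        weights=weights,
        margin=margin,
        n_training_examples=len(articles),
        seed=seed,
    )


def classify_subject(
    model: SubjectModel, article: NewsArticle
) -> tuple[str, dict[str, float]]:
    """Label one article: argmax category, or "other" below the margin.

    Returns the label and the per-category one-vs-rest probabilities.
    Exact ties break alphabetically (and are logged).
    """
    if not model.vocabulary:
        raise ValueError("unfitted model: empty vocabulary")
    vec = _vectorizer(vocabulary=model.vocabulary)
    x = vec.transform([f"{article.title} {article.body}"])
    scores: dict[str, float] = {}
    for cat in SUBJECT_CATEGORIES:
        z = model.intercepts[cat] + float((x @ model.weights[cat])[0])
        scores[cat] = float(0.5 * (1.0 + np.tanh(z / 2.0)))
    best = max(scores.values())
    top = sorted(cat for cat, s in scores.items() if s == best)
    if len(top) > 1:
        logger.info("article %s: tie between %s; choosing %s", article.id, top, top[0])
    label = top[0] if best >= model.margin else OTHER
    return label, scores


def subject_distribution(
    labels: Sequence[str], include_other: bool = True
) -> list[tuple[str, float]]:
    """(label, percentage) pairs, percentages over ALL articles.

    With ``include_other=False`` the "other" row is dropped but percentages
    keep the full denominator, so the shown shares need not sum to 100.
    """
    if not labels:
        raise ValueError("empty label sequence")
    tally = Counter(labels)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    out = [(lab, 100.0 * n / len(labels)) for lab, n in ranked
           if include_other or lab != OTHER]
    return out
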