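"""Primarily-ENDS-focused scoring.

An article that merely mentions the product once in passing is not *about*
it. The relevance score combines how often the product is mentioned and how
early the first mention appears: a logistic regression on
(log mention count, first-mention position, title hit) with weights fit to
annotated examples and a probability cutoff (default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.linear_model import LogisticRegression

from .corpus import NewsArticle
from .keywords import MentionSpan

FEATURE_NAMES = ("log_mention_count", "first_position", "title_hit")


@dataclass(frozen=True)
class RelevanceFeatures:
    """Mention-count and mention-position features for one article.

    ``first_position`` is 1 - (offset of earliest body mention / body length),
    so 1.0 means the article opens with the product and 0.0 means no body
    mention at all.
    """

    mention_count: int
    log_mention_count: float
    first_position: float
    title_hit: int

    def as_vector(self) -> np.ndarray:
        return np.array([self.log_mention_count, self.first_position, self.title_hit],
                        dtype=float)


def extract_relevance_features(
    article: NewsArticle, spans: Sequence[MentionSpan]
) -> RelevanceFeatures:
    """Deterministic feature vector from an article's mention spans."""
    body_spans = [s for s in spans if s.field == "body"]
    title_hit = int(any(s.field == "title" for s in spans))
    if body_spans:
        if len(article.body) == 0:
            raise ValueError(f"article {article.id}: body spans claimed on empty body")
        earliest = min(s.start for s in body_spans)
        first_position = 1.0 - earliest / len(article.body)
    else:
        first_position = 0.0
    n = len(spans)
    return RelevanceFeatures(
        mention_count=n,
        log_mention_count=math.log1p(n),
        first_position=first_position,
        title_hit=title_hit,
    )


@dataclass
class RelevanceModel:
    """Fitted logistic weights: intercept + one weight per feature."""

    weights: np.ndarray  # shape (1 + n_features,)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (1 + len(FEATURE_NAMES),):
            raise ValueError(
                f"expected {1 + len(FEATURE_NAMES)} weights, got {self.weights.shape}"
            )
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    def save(self, path: Union[str, Path]) -> None:
        """Persist as a small key-value text file (name<TAB>value)."""
        lines = [f"intercept\t{float(self.weights[0])!r}"]
        lines += [f"{name}\t{float(w)!r}"
                  for name, w in zip(FEATURE_NAMES, self.weights[1:])]
        lines.append(f"threshold\t{float(self.threshold)!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RelevanceModel":
        kv = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                k, v = line.split("\t")
                kv[k] = float(v)
        weights = [kv["intercept"]] + [kv[n] for n in FEATURE_NAMES]
        return cls(weights=np.array(weights), threshold=kv.get("threshold", 0.5))


def fit_relevance_weights(
    features: Sequence[RelevanceFeatures],
    focus_truth: Sequence[bool],
    threshold: float = 0.5,
) -> RelevanceModel:
    """Fit the logistic weights by maximum likelihood.

    Unpenalized binary logistic regression (lbfgs, gradient tolerance 1e-6);
    deterministic given the data. Requires both classes present.
    """
    if len(features) != len(focus_truth):
        raise ValueError("features and focus_truth length mismatch")
    X = np.array([f.as_vector() for f in features])
    y = np.asarray(focus_truth, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-6, max_iter=10_000)
    clf.fit(X, y)
    weights = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return RelevanceModel(weights=weights, threshold=threshold)


def score_relevance(
    model: RelevanceModel, features: RelevanceFeatures
) -> tuple[float, bool]:
    """Probability the article is primarily ENDS-focused, and the decision."""
    z = model.weights[0] + float(model.weights[1:] @ features.as_vector())
    # numerically stable inverse-logit
    p = 0.5 * (1.0 + math.tanh(z / 2.0))
    return p, p >= model.threshold


@dataclass(frozen=True)
class PrecisionReport:
    """Positive-predictive-value tally. precision is None when TP+FP = 0."""

    true_positives: int
    false_positives: int
    precision: Optional[float]


def evaluate_precision(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> PrecisionReport:
    """Precision (PPV) of boolean predictions against reference truth."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth length mismatch")
    tp = sum(1 for p, t in zip(predicted, truth) if p and t)
    fp = sum(1 for p, t in zip(predicted, truth) if p and not t)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    return PrecisionReport(true_positives=tp, false_positives=fp, precision=precision)
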