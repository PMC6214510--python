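"""Trending (popularity) score.

Popularity is measured in two dimensions — source PageRank and social-media
shares (Twitter + Facebook, summed) — each studentized corpus-wide and
combined with equal weight. Articles are ranked into deciles; "popular"
means landing in the top three deciles (decile rank >= 8).

A three-way variant (Twitter and Facebook studentized separately) is
available behind a flag; the two-dimension form is the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import Counter
from typing import Sequence

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

POPULAR_DECILE_CUTOFF = 8


def studentize(values: Sequence[float]) -> np.ndarray:
    """Center by the sample mean, scale by the sample SD (n-1 denominator).

    Output has mean 0 and sample SD 1. Degenerate spread (SD = 0) maps
    everything to 0 with a warning. Requires n >= 2.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("studentize requires a 1-D sample of size >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate spread: all %d values identical; returning zeros", x.size)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class TrendingScore:
    """Studentized popularity components and the combined score for one article."""

    article_id: str
    z_pagerank: float
    z_shares: float
    score: float          # equal-weight mean of the studentized components
    decile: int           # 1..10 by corpus-wide rank
    popular: bool         # decile >= 8 ("top 3 deciles")


def trending_scores(
    articles: Sequence, three_way: bool = False
) -> list[TrendingScore]:
    """Score a corpus: studentize signals, combine, rank into deciles.

    ``articles`` need ``id``, ``pagerank``, ``twitter_shares`` and
    ``facebook_shares`` attributes. Deciles partition the corpus into
    near-equal tenths (sizes differ by at most 1); score ties resolve by
    stable article-id order.
    """
    n = len(articles)
    if n < 2:
        raise ValueError("trending_scores requires >= 2 articles")
    z_pr = studentize([a.pagerank for a in articles])
    if three_way:
        z_tw = studentize([a.twitter_shares for a in articles])
        z_fb = studentize([a.facebook_shares for a in articles])
        z_sh = (z_tw + z_fb) / 2.0
        scores = (z_pr + z_tw + z_fb) / 3.0
    else:
        z_sh = studentize([a.twitter_shares + a.facebook_shares for a in articles])
        scores = (z_pr + z_sh) / 2.0
    order = sorted(range(n), key=lambda i: (scores[i], articles[i].id))
    deciles = np.empty(n, dtype=int)
    for rank, i in enumerate(order):
        deciles[i] = rank * 10 // n + 1
    return [
        TrendingScore(
            article_id=articles[i].id,
            z_pagerank=float(z_pr[i]),
            z_shares=float(z_sh[i]),
            score=float(scores[i]),
            decile=int(deciles[i]),
            popular=bool(deciles[i] >= POPULAR_DECILE_CUTOFF),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SubjectPopularity:
    """P(popular | subject) with a 95% CI from a single-dummy logistic model."""

    subject: str
    probability: float
    ci_low: float
    ci_high: float
    n: int


def _invlogit(z: float) -> float:
    return float(0.5 * (1.0 + np.tanh(z / 2.0)))


def popularity_by_subject(
    labels: Sequence[str], popular_flags: Sequence[bool]
) -> list[SubjectPopularity]:
    """Per subject: a separate logistic regression of popular on that
    subject's dummy indicator; the reported probability is the inverse-logit
    at dummy = 1 (equal, in this saturated model, to the subject's empirical
    popular proportion). The 95% CI is a normal approximation on the logit
    scale, transformed back, hence inside [0, 1].

    Subjects whose articles are all popular or none popular get probability
    1 or 0 with a separation warning and a degenerate CI.
    """
    if len(labels) != len(popular_flags):
        raise ValueError("labels and popular_flags length mismatch")
    if not labels:
        raise ValueError("empty input")
    y = np.asarray(popular_flags, dtype=float)
    labs = np.asarray(labels)
    out: list[SubjectPopularity] = []
    for subject in sorted(Counter(labels)):
        dummy = (labs == subject).astype(float)
        n1 = int(dummy.sum())
        k1 = int(y[dummy == 1].sum())
        n0 = len(y) - n1
        k0 = int(y.sum()) - k1
        if k1 == 0 or k1 == n1:
            p = k1 / n1
            logger.warning("subject %r: complete separation (%d/%d popular)", subject, k1, n1)
            out.append(SubjectPopularity(subject, float(p), float(p), float(p), n1))
            continue
        if n0 == 0 or k0 == 0 or k0 == n0:
            # the complement cell separates instead; in this saturated model
            # the subject cell's ML estimate and information are closed-form
            p = k1 / n1
            eta = math.log(p / (1 - p))
            se = math.sqrt(1.0 / (n1 * p * (1 - p)))
        else:
            X = sm.add_constant(dummy)
            fit = sm.Logit(y, X).fit(disp=0)
            eta = float(fit.params[0] + fit.params[1])
            var = float(fit.cov_params()[0, 0] + fit.cov_params()[1, 1]
                        + 2.0 * fit.cov_params()[0, 1])
            se = np.sqrt(var)
        out.append(SubjectPopularity(
            subject=subject,
            probability=_invlogit(eta),
            ci_low=_invlogit(eta - 1.959963984540054 * se),
            ci_high=_invlogit(eta + 1.959963984540054 * se),
            n=n1,
        ))
    return out
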