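"""Held-out evaluation experiments on seeded synthetic corpora.

Each experiment generates a corpus with known ground truth, runs the
corresponding pipeline stage, and measures precision (positive predictive
value) against the truth — the same figure of merit used to validate the
pipeline's automated stages against human annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import MULTINATIONAL, Gazetteer, extract_entities, resolve_geo_focus
from .keywords import KeywordTable, filter_corpus
from .popularity import popularity_by_subject, trending_scores
from .relevance import (
    evaluate_precision,
    extract_relevance_features,
    fit_relevance_weights,
    score_relevance,
)
from .subject import adjudicate_labels, classify_subject, train_subject_classifier
from .synthetic import GeneratorConfig, generate_corpus, simulate_annotations
from .trends import daily_counts, fit_trend

#: 10 focal countries plus a multinational class, for geo evaluation.
GEO_EVAL_MIXTURE = {
    "USA": 0.25, "GBR": 0.10, "RUS": 0.08, "EGY": 0.07, "CHN": 0.07,
    "UKR": 0.06, "IND": 0.06, "PRY": 0.05, "IDN": 0.03, "VNM": 0.03,
    MULTINATIONAL: 0.20,
}


@dataclass(frozen=True)
class ExperimentResult:
    value: float
    n: int


def micro_precision(predicted, truth) -> float:
    """Micro-averaged precision over all classes.

    With every item receiving exactly one prediction, summing true and false
    positives over classes makes micro-averaged precision equal to accuracy.
    """
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def _split(n: int, train_frac: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    cut = int(round(train_frac * n))
    return idx[:cut], idx[cut:]


def relevance_precision_experiment(
    n_articles: int = 2000, seed: int = 0, train_frac: float = 0.7
) -> ExperimentResult:
    """Held-out precision of the primarily-focused classifier.

    Generates a 50/50 focused/distractor corpus, fits the relevance weights
    on 70%, and scores precision on the held-out 30% at the default cutoff.
    """
    cfg = GeneratorConfig(n_articles=n_articles, seed=seed, distractor_fraction=0.5)
    articles, labels = generate_corpus(cfg)
    truth = {l.article_id: l.focus_truth for l in labels}
    kept, spans = filter_corpus(articles, KeywordTable.bundled())
    feats = [extract_relevance_features(a, spans[a.id]) for a in kept]
    y = [truth[a.id] for a in kept]
    rng = np.random.default_rng(seed + 1)
    train, test = _split(len(kept), train_frac, rng)
    model = fit_relevance_weights([feats[i] for i in train], [y[i] for i in train])
    predicted = [score_relevance(model, feats[i])[1] for i in test]
    report = evaluate_precision(predicted, [y[i] for i in test])
    return ExperimentResult(value=report.precision, n=len(test))


def geo_precision_experiment(n_articles: int = 2000, seed: int = 0) -> ExperimentResult:
    """Micro-averaged precision of the geographic-focus resolver against
    generator truth, on a 10-country + multinational mixture."""
    cfg = GeneratorConfig(n_articles=n_articles, seed=seed,
                          geo_mixture=dict(GEO_EVAL_MIXTURE))
    articles, labels = generate_corpus(cfg)
    truth = {l.article_id: l.geo_truth for l in labels}
    gaz = Gazetteer.bundled()
    predicted = [resolve_geo_focus(extract_entities(a.title, a.body, gaz))
                 for a in articles]
    value = micro_precision(predicted, [truth[a.id] for a in articles])
    return ExperimentResult(value=value, n=n_articles)


def subject_precision_experiment(
    n_articles: int = 3000, seed: int = 0, disagreement_rate: float = 0.05,
    train_frac: float = 0.7
) -> ExperimentResult:
    """Held-out micro-averaged precision of the subject classifier trained on
    adjudicated two-annotator labels (5% disagreement by default)."""
    cfg = GeneratorConfig(n_articles=n_articles, seed=seed)
    articles, labels = generate_corpus(cfg)
    truth = [l.subject_truth for l in labels]
    pairs = simulate_annotations(truth, disagreement_rate, seed=seed + 1)
    adjudicated = [adjudicate_labels(a, b) for a, b in pairs]
    rng = np.random.default_rng(seed + 2)
    train, test = _split(n_articles, train_frac, rng)
    model = train_subject_classifier(
        [articles[i] for i in train], [adjudicated[i] for i in train], seed=seed)
    predicted = [classify_subject(model, articles[i])[0] for i in test]
    value = micro_precision(predicted, [adjudicated[i] for i in test])
    return ExperimentResult(value=value, n=len(test))


def popularity_recovery_experiment(
    n_articles: int = 5000, seed: int = 0, subject: str = "quitting"
) -> dict:
    """Estimate P(popular | subject) on a generated corpus and report it with
    the logistic model's 95% CI; the generator's configured probability for
    that subject is returned alongside for comparison."""
    cfg = GeneratorConfig(n_articles=n_articles, seed=seed)
    articles, labels = generate_corpus(cfg)
    truth = {l.article_id: l.subject_truth for l in labels}
    scores = trending_scores(articles)
    flags = [s.popular for s in scores]
    subj_labels = [truth[a.id] for a in articles]
    rows = {r.subject: r for r in popularity_by_subject(subj_labels, flags)}
    r = rows[subject]
    return {
        "estimate": r.probability,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "configured": cfg.popular_subject_probs[subject],
        "n_subject": r.n,
    }


def volume_recovery_experiment(seed: int = 0) -> dict:
    """Recover configured yearly volume means (8 and 75 articles/day) from a
    Poisson-volume corpus covering half of each of two years."""
    import datetime as dt

    cfg = GeneratorConfig(
        n_articles=None,
        start_date=dt.date(2013, 7, 1),
        end_date=dt.date(2014, 6, 30),
        yearly_volume_means={2013: 8.0, 2014: 75.0},
        seed=seed,
    )
    articles, _ = generate_corpus(cfg)
    series = daily_counts(articles, cfg.start_date, cfg.end_date)
    fit = fit_trend(series)
    stats = {y.year: y for y in fit.yearly}
    return {
        "mean_2013": stats[2013].mean,
        "mean_2014": stats[2014].mean,
        "n_days_2013": stats[2013].n_days,
        "n_days_2014": stats[2014].n_days,
        "n_articles": len(articles),
    }
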