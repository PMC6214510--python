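"""Synthetic news-corpus generator with known ground truth.

Articles are assembled from template sentence pools rather than a language
model, so every truth the pipeline is asked to recover is realized by
construction and fully seedable:

* **Relevance.** Primarily-focused articles carry >= 3 product mentions with
  the first at the very start of the body and (usually) a title mention;
  incidental "distractor" articles carry exactly one mention in the final
  30% of the body and none in the title.
* **Geography.** The focal country appears as gazetteer entities holding at
  least a 2:1 mention lead over any other country; multinational articles
  name two countries with equal tallies.
* **Subject.** Each category injects sentences built from that category's
  private vocabulary; "other" articles get none.
* **Sentiment.** Lexicon words are mixed so the article's mean sentence
  score lands within a few hundredths of its target.
* **Popularity.** A latent "buzz" variable, drawn per subject from a
  top-30%/bottom-70% band mixture, drives both PageRank and (log-normal,
  right-skewed) share counts, so P(popular | subject) is a config parameter.

Word pools are mutually disjoint and avoid keyword, gazetteer, and lexicon
collisions, which is what makes the ground-truth labels recoverable.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .corpus import LabeledArticle, NewsArticle
from .geo import MULTINATIONAL, UNKNOWN, Gazetteer
from .keywords import ENGLISH_TERMS
from .sentiment import SentimentLexicon
from .subject import OTHER, SUBJECT_CATEGORIES

# ---------------------------------------------------------------------------
# default study conditions (a corpus shaped like the published composition)

DEFAULT_YEARLY_MEANS = {2013: 8.0, 2014: 36.0, 2015: 47.0, 2016: 51.0,
                        2017: 57.0, 2018: 75.0}

DEFAULT_GEO_MIXTURE = {
    "USA": 0.34, "GBR": 0.07, "CAN": 0.05, "AUS": 0.05, "RUS": 0.04,
    "FRA": 0.04, "EGY": 0.03, "CHN": 0.02, "UKR": 0.02, "IND": 0.01,
    "PRY": 0.01, "IDN": 0.01, "VNM": 0.01, MULTINATIONAL: 0.30,
}

DEFAULT_SUBJECT_MIXTURE = {
    "warnings": 0.18, "bans": 0.13, "prices": 0.09, "industry": 0.08,
    "prevalence": 0.06, "quitting": 0.04, "marketing": 0.02,
    "flavor": 0.01, "age": 0.01, OTHER: 0.38,
}

#: P(popular | subject) for the substantive categories; the "other" class is
#: balanced at generation time so the aggregate popular rate is 0.30 (the
#: top-3-deciles mass). Values echo the published per-subject spread
#: (quitting highest at 0.13, industry lowest at 0.05).
DEFAULT_POPULAR_PROBS = {
    "quitting": 0.13, "warnings": 0.12, "bans": 0.12, "prices": 0.08,
    "prevalence": 0.07, "marketing": 0.06, "flavor": 0.06, "age": 0.06,
    "industry": 0.05,
}

#: Private vocabulary per subject category: disjoint across categories and
#: from the keyword list, the bundled gazetteer, and the bundled lexicon.
SUBJECT_VOCAB = {
    "prevalence": ("survey", "respondents", "percentage", "usage", "estimates", "prevalence"),
    "bans": ("prohibited", "indoor", "ordinance", "restriction", "smokefree", "bylaw"),
    "quitting": ("quit", "cessation", "smokers", "abstinence", "quitline", "switching"),
    "warnings": ("advisory", "toxicology", "caution", "nicotine", "exposure", "inhalation"),
    "marketing": ("advertising", "billboard", "promotion", "sponsorship", "commercials", "influencers"),
    "prices": ("tax", "levy", "excise", "tariff", "pricing", "surcharge"),
    "age": ("minors", "underage", "verification", "eighteen", "curfew", "identification"),
    "flavor": ("flavored", "menthol", "mango", "candy", "fruity", "aromas"),
    "industry": ("manufacturer", "revenue", "corporate", "brands", "merger", "shareholders"),
}

_FILLERS = (
    "The committee met again on Tuesday to continue its review.",
    "A spokesperson said further details would follow next month.",
    "The document runs to several hundred pages.",
    "Local reporters attended the briefing throughout the afternoon.",
    "The agenda covered a range of administrative items.",
    "Officials took questions for about an hour.",
    "The session adjourned shortly before noon.",
    "Minutes of the meeting will be published online.",
    "Several residents spoke during the open comment period.",
    "The panel will reconvene after the summer recess.",
    "Staff circulated the draft to members in advance.",
    "The proposal now moves to a second reading.",
)

_POS_SENT = "Commentators called the development {w}."
_NEG_SENT = "Analysts described the situation as {w}."


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_articles: Optional[int] = 2000
    start_date: _dt.date = _dt.date(2013, 1, 1)
    end_date: _dt.date = _dt.date(2018, 7, 31)
    yearly_volume_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_YEARLY_MEANS))
    weekday_weights: tuple[float, ...] = (1.0,) * 7
    distractor_fraction: float = 0.5
    geo_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GEO_MIXTURE))
    subject_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECT_MIXTURE))
    sentiment_mean: float = -0.042
    sentiment_sd: float = 0.16
    popular_subject_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POPULAR_PROBS))
    overall_popular_rate: float = 0.30
    share_log_mean: float = 3.0
    share_log_sd: float = 1.5
    pagerank_range: tuple[float, float] = (0.0, 10.0)
    languages: tuple[str, ...] = ("en",)
    title_mention_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("geo_mixture", self.geo_mixture),
                          ("subject_mixture", self.subject_mixture)):
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1, got {sum(mix.values())}")
        if not 0.0 <= self.distractor_fraction <= 1.0:
            raise ValueError("distractor_fraction must be in [0, 1]")
        if self.start_date > self.end_date:
            raise ValueError("empty date window")


def _day_weights(cfg: GeneratorConfig) -> tuple[list[_dt.date], np.ndarray]:
    days = []
    weights = []
    d = cfg.start_date
    while d <= cfg.end_date:
        w = cfg.yearly_volume_means.get(d.year, 1.0) * cfg.weekday_weights[d.weekday()]
        days.append(d)
        weights.append(w)
        d += _dt.timedelta(days=1)
    return days, np.asarray(weights, dtype=float)


def _balanced_popular_probs(cfg: GeneratorConfig) -> dict[str, float]:
    """Per-subject band probabilities with "other" set so the mixture-wide
    popular rate matches ``overall_popular_rate`` (keeping the decile cutoff
    aligned with the band boundary)."""
    probs = dict(cfg.popular_subject_probs)
    pi_other = cfg.subject_mixture.get(OTHER, 0.0)
    contributed = sum(cfg.subject_mixture.get(s, 0.0) * p for s, p in probs.items())
    if pi_other > 0:
        p_other = (cfg.overall_popular_rate - contributed) / pi_other
        probs[OTHER] = min(max(p_other, 0.0), 1.0)
    return probs


def _pick(rng: np.random.Generator, mixture: dict[str, float]) -> str:
    keys = sorted(mixture)
    p = np.array([mixture[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


class _CountrySurfaces:
    """Reverse lookup: alpha-3 code -> display surface forms."""

    def __init__(self, gazetteer: Gazetteer):
        self.by_code: dict[str, list[str]] = {}
        for surface, code in gazetteer.surface_forms.items():
            self.by_code.setdefault(code, []).append(surface.title())

    def surface(self, rng: np.random.Generator, code: str) -> str:
        forms = self.by_code.get(code)
        if not forms:
            raise ValueError(f"no gazetteer surface form for {code}")
        return forms[rng.integers(len(forms))]


def _keyword_term(rng: np.random.Generator, language: str) -> str:
    if language == "xx":
        return ("zvapium", "zvapiums", "zcigeon")[rng.integers(3)]
    return ENGLISH_TERMS[rng.integers(len(ENGLISH_TERMS))]


def _sentiment_sentences(rng: np.random.Generator, target: float, n_zero: int,
                         lexicon: SentimentLexicon) -> tuple[list[str], float]:
    """Signed sentences (score exactly +-1 each) so the article mean over
    ``n_zero`` zero-score sentences plus these lands near ``target``."""
    pos_words = sorted(t for t, w in lexicon.polarities.items() if w > 0)
    neg_words = sorted(t for t, w in lexicon.polarities.items() if w < 0)
    t = float(np.clip(target, -0.75, 0.75))
    m = int(round(n_zero * abs(t) / (1.0 - abs(t)))) if t != 0 else 0
    template = _POS_SENT if t > 0 else _NEG_SENT
    words = pos_words if t > 0 else neg_words
    sentences = [template.format(w=words[rng.integers(len(words))]) for _ in range(m)]
    achieved = math.copysign(m / (n_zero + m), t) if m else 0.0
    return sentences, achieved


def generate_corpus(
    config: Optional[GeneratorConfig] = None,
    gazetteer: Optional[Gazetteer] = None,
    lexicon: Optional[SentimentLexicon] = None,
) -> tuple[list[NewsArticle], list[LabeledArticle]]:
    """Generate a corpus and its ground-truth sidecar. Deterministic per seed."""
    cfg = config or GeneratorConfig()
    gaz = gazetteer or Gazetteer.bundled()
    lex = lexicon or SentimentLexicon.bundled()
    rng = np.random.default_rng(cfg.seed)
    surfaces = _CountrySurfaces(gaz)
    pop_probs = _balanced_popular_probs(cfg)

    days, weights = _day_weights(cfg)
    if cfg.n_articles is not None:
        idx = rng.choice(len(days), size=cfg.n_articles, p=weights / weights.sum())
        dates = [days[i] for i in idx]
    else:
        # Poisson volume model: weekday weights modulate within-year rates
        wk = np.asarray(cfg.weekday_weights, dtype=float)
        wk = wk * 7.0 / wk.sum()
        dates = []
        for d in days:
            rate = cfg.yearly_volume_means.get(d.year, 0.0) * wk[d.weekday()]
            dates.extend([d] * int(rng.poisson(rate)))

    articles: list[NewsArticle] = []
    labels: list[LabeledArticle] = []
    for i, date in enumerate(dates):
        art_id = f"syn-{i:06d}"
        language = cfg.languages[rng.integers(len(cfg.languages))]
        focused = rng.random() >= cfg.distractor_fraction
        subject = _pick(rng, cfg.subject_mixture)
        geo = _pick(rng, cfg.geo_mixture)
        target_sent = float(np.clip(
            rng.normal(cfg.sentiment_mean, cfg.sentiment_sd), -0.75, 0.75))

        # ---- latent buzz -> popularity signals --------------------------
        p_pop = pop_probs.get(subject, cfg.overall_popular_rate)
        if rng.random() < p_pop:
            u = rng.uniform(1.0 - cfg.overall_popular_rate, 1.0)
        else:
            u = rng.uniform(0.0, 1.0 - cfg.overall_popular_rate)
        lo, hi = cfg.pagerank_range
        u_pr = float(np.clip(u + rng.normal(0, 0.01), 0.0, 1.0))
        pagerank = lo + (hi - lo) * u_pr
        u_sh = float(np.clip(u + rng.normal(0, 0.01), 1e-6, 1.0 - 1e-6))
        total_shares = int(round(math.exp(
            cfg.share_log_mean + cfg.share_log_sd * norm.ppf(u_sh))))
        twitter = int(rng.binomial(total_shares, 0.5))
        facebook = total_shares - twitter

        # ---- text assembly ---------------------------------------------
        zero_sents: list[str] = []   # sentences guaranteed to score 0

        # geography
        if geo == MULTINATIONAL:
            countries = [c for c in sorted(cfg.geo_mixture) if c != MULTINATIONAL]
            a, b = rng.choice(len(countries), size=2, replace=False)
            per = int(rng.integers(2, 4))
            geo_sents = []
            for code in (countries[a], countries[b]):
                geo_sents += [f"Regulators in {surfaces.surface(rng, code)} reviewed the rules."
                              for _ in range(per)]
        elif geo == UNKNOWN:
            geo_sents = []
        else:
            m = int(rng.integers(2, 6))
            geo_sents = [f"Regulators in {surfaces.surface(rng, geo)} reviewed the rules."
                         for _ in range(m)]
            if rng.random() < 0.5:
                others = [c for c in sorted(cfg.geo_mixture)
                          if c not in (geo, MULTINATIONAL, UNKNOWN)]
                sec = others[rng.integers(len(others))]
                geo_sents += [f"Delegates from {surfaces.surface(rng, sec)} also attended."
                              for _ in range(m // 2)]
        zero_sents.extend(geo_sents)

        # subject vocabulary
        if subject != OTHER:
            vocab = SUBJECT_VOCAB[subject]
            for _ in range(4):
                w = rng.choice(len(vocab), size=3, replace=False)
                zero_sents.append(
                    f"The {vocab[w[0]]} measure addressed {vocab[w[1]]} and {vocab[w[2]]}.")

        # filler
        n_fill = int(rng.integers(8, 13))
        zero_sents.extend(_FILLERS[rng.integers(len(_FILLERS))] for _ in range(n_fill))

        # product mentions
        term = _keyword_term(rng, language)
        if focused:
            mention_sents = [f"{term.capitalize()} regulation dominated the agenda."]
            n_extra = int(rng.integers(2, 5))
            mention_sents += [f"Speakers returned to {term} several times."
                              for _ in range(n_extra)]
            title_term = rng.random() < cfg.title_mention_prob
            title = (f"{term.capitalize()} debate intensifies"
                     if title_term else "Regulatory debate intensifies")
        else:
            mention_sents = [f"One attendee briefly mentioned {term} in passing."]
            title = "Council session covers routine business"

        # order the body: focused leads with the product, distractors bury
        # their single mention at the end
        perm = rng.permutation(len(zero_sents))
        shuffled = [zero_sents[j] for j in perm]
        if focused:
            body_zero = [mention_sents[0]] + shuffled
            insert_at = rng.integers(1, len(body_zero) + 1, size=len(mention_sents) - 1)
            for k, s in zip(sorted(insert_at, reverse=True), mention_sents[1:]):
                body_zero.insert(int(k), s)
        else:
            body_zero = shuffled + mention_sents

        n_zero = len(body_zero) + 1  # +1: the title is a scored sentence too
        sent_sents, achieved = _sentiment_sentences(rng, target_sent, n_zero, lex)
        # distractor keeps its lone mention last so it stays in the tail 30%
        tail = [] if focused else [body_zero.pop()]
        low = 1 if focused else 0  # keep the lead product mention first
        insert_positions = sorted(
            (int(p) for p in rng.integers(low, len(body_zero) + 1, size=len(sent_sents))),
            reverse=True)
        for p, s in zip(insert_positions, sent_sents):
            body_zero.insert(p, s)
        body = " ".join(body_zero + tail)

        articles.append(NewsArticle(
            id=art_id,
            url=f"https://news.example.org/{art_id}",
            source=f"outlet-{rng.integers(0, 50):02d}",
            published_at=date,
            language=language,
            title=title,
            body=body,
            pagerank=round(pagerank, 3),
            twitter_shares=twitter,
            facebook_shares=facebook,
        ))
        labels.append(LabeledArticle(
            article_id=art_id,
            focus_truth=bool(focused),
            geo_truth=geo,
            subject_truth=subject,
            sentiment_truth=round(achieved, 4),
        ))
    return articles, labels


def simulate_annotations(
    truths: Sequence[str], disagreement_rate: float = 0.05, seed: int = 0
) -> list[tuple[str, str]]:
    """Two-annotator labels per article: annotator A reports the truth;
    annotator B deviates to a uniformly random different label at the
    configured disagreement rate."""
    rng = np.random.default_rng(seed)
    out = []
    pool = list(SUBJECT_CATEGORIES) + [OTHER]
    for truth in truths:
        a = truth
        if rng.random() < disagreement_rate:
            alternatives = [l for l in pool if l != truth]
            b = alternatives[rng.integers(len(alternatives))]
        else:
            b = truth
        out.append((a, b))
    return out


def generate_fixtures(
    out_dir: Union[str, Path],
    subject_truths: Optional[Sequence[tuple[str, str]]] = None,
    disagreement_rate: float = 0.05,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the default data files (keyword table, gazetteer, lexicon) and,
    when ``subject_truths`` [(article_id, label), ...] is given, a
    two-annotator annotation file at the configured disagreement rate.

    Returns a name -> path map.
    """
    from importlib import resources

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("keywords.tsv", "gazetteer.tsv", "lexicon.tsv"):
        ref = resources.files("endsmonitor.data") / name
        dest = out_dir / name
        dest.write_text(ref.read_text(encoding="utf-8"), encoding="utf-8")
        written[name] = dest
    if subject_truths is not None:
        ids = [i for i, _ in subject_truths]
        pairs = simulate_annotations([t for _, t in subject_truths],
                                     disagreement_rate, seed)
        lines = ["article_id\tannotator_id\tlabel"]
        for art_id, (a, b) in zip(ids, pairs):
            lines.append(f"{art_id}\tA\t{a}")
            lines.append(f"{art_id}\tB\t{b}")
        dest = out_dir / "annotations.tsv"
        dest.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written["annotations.tsv"] = dest
    return written
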