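"""End-to-end orchestration: generate/read -> filter -> relevance -> geo ->
subject -> popularity -> sentiment -> report.

A run is governed by one :class:`RunConfig`; the manifest records per-stage
input/output counts, the parameters, the seed, and a hash of the resolved
configuration, which together suffice to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import corpus as corpus_io
from . import geo as geo_mod
from . import relevance as rel_mod
from . import sentiment as sent_mod
from . import subject as subj_mod
from . import synthetic as syn_mod
from . import trends as trends_mod
from . import popularity as pop_mod
from .keywords import KeywordTable, filter_corpus

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    output_dir: Union[str, Path] = "endsmonitor-run"
    corpus_path: Optional[Union[str, Path]] = None   # None -> generate
    labels_path: Optional[Union[str, Path]] = None
    keyword_table_path: Optional[Union[str, Path]] = None
    gazetteer_path: Optional[Union[str, Path]] = None
    lexicon_path: Optional[Union[str, Path]] = None
    n_articles: int = 2000
    seed: int = 0
    # stage toggles
    relevance_enabled: bool = True
    geo_enabled: bool = True
    subject_enabled: bool = True
    popularity_enabled: bool = True
    sentiment_enabled: bool = True
    # thresholds
    relevance_threshold: float = 0.5
    subject_margin: float = subj_mod.DEFAULT_MARGIN
    sentiment_strong: float = 0.5
    sentiment_neutral_band: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.relevance_threshold < 1.0:
            raise ValueError("relevance_threshold must be in (0, 1)")
        for p in (self.corpus_path, self.labels_path, self.keyword_table_path,
                  self.gazetteer_path, self.lexicon_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages in order; returns (and writes) the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "parameters": {
            "relevance_threshold": cfg.relevance_threshold,
            "subject_margin": cfg.subject_margin,
            "sentiment_strong": cfg.sentiment_strong,
            "sentiment_neutral_band": cfg.sentiment_neutral_band,
        },
        "stages": {},
    }

    def _stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    # -- corpus --------------------------------------------------------
    try:
        if cfg.corpus_path is None:
            gen_cfg = syn_mod.GeneratorConfig(n_articles=cfg.n_articles, seed=cfg.seed)
            articles, truth = syn_mod.generate_corpus(gen_cfg)
            corpus_io.write_corpus(articles, out / "corpus.jsonl")
            corpus_io.write_labels(truth, out / "labels.jsonl")
        else:
            articles, skipped = corpus_io.read_corpus(cfg.corpus_path, strict=False)
            truth = (corpus_io.read_labels(cfg.labels_path)
                     if cfg.labels_path else [])
        truth_by_id = {t.article_id: t for t in truth}
        _stage("corpus", articles=len(articles), labels=len(truth))
    except Exception:
        logger.exception("stage corpus failed")
        raise

    table = (KeywordTable.from_tsv(cfg.keyword_table_path)
             if cfg.keyword_table_path else KeywordTable.bundled())
    gazetteer = (geo_mod.Gazetteer.from_tsv(cfg.gazetteer_path)
                 if cfg.gazetteer_path else geo_mod.Gazetteer.bundled())
    lexicon = (sent_mod.SentimentLexicon.from_tsv(cfg.lexicon_path)
               if cfg.lexicon_path else sent_mod.SentimentLexicon.bundled())

    # -- keyword filter ------------------------------------------------
    matched, spans_by_id = [], {}
    try:
        matched, spans_by_id = filter_corpus(articles, table)
        _stage("keyword_filter", input=len(articles), matched=len(matched))
    except Exception:
        logger.exception("stage keyword_filter failed")
        raise

    # -- relevance -----------------------------------------------------
    focused = matched
    if cfg.relevance_enabled:
        try:
            feats = [rel_mod.extract_relevance_features(a, spans_by_id[a.id])
                     for a in matched]
            have_truth = [i for i, a in enumerate(matched)
                          if truth_by_id.get(a.id) is not None
                          and truth_by_id[a.id].focus_truth is not None]
            if len(have_truth) >= 4:
                model = rel_mod.fit_relevance_weights(
                    [feats[i] for i in have_truth],
                    [truth_by_id[matched[i].id].focus_truth for i in have_truth],
                    threshold=cfg.relevance_threshold)
                model.save(out / "relevance_model.tsv")
                decisions = [rel_mod.score_relevance(model, f)[1] for f in feats]
                focused = [a for a, keep in zip(matched, decisions) if keep]
                _stage("relevance", input=len(matched), focused=len(focused))
            else:
                logger.warning("relevance: no focus truth available; stage skipped")
                _stage("relevance", skipped=True, input=len(matched))
        except Exception:
            logger.exception("stage relevance failed")
            raise
    else:
        _stage("relevance", skipped=True, input=len(matched))

    # -- geography -----------------------------------------------------
    geo_labels: list[str] = []
    if cfg.geo_enabled:
        geo_labels = [geo_mod.resolve_geo_focus(
            geo_mod.extract_entities(a.title, a.body, gazetteer)) for a in focused]
        _stage("geo", input=len(focused), resolved=len(geo_labels))

    # -- subject -------------------------------------------------------
    subject_labels: list[str] = []
    if cfg.subject_enabled:
        train_idx = [i for i, a in enumerate(focused)
                     if truth_by_id.get(a.id) is not None
                     and truth_by_id[a.id].subject_truth is not None]
        try:
            if train_idx:
                # demo corpora are small; tolerate thin rare categories
                model = subj_mod.train_subject_classifier(
                    [focused[i] for i in train_idx],
                    [truth_by_id[focused[i].id].subject_truth for i in train_idx],
                    seed=cfg.seed, margin=cfg.subject_margin, min_per_category=2)
                model.save(out / "subject_model.json")
                subject_labels = [subj_mod.classify_subject(model, a)[0]
                                  for a in focused]
                _stage("subject", input=len(focused), labeled=len(subject_labels))
            else:
                logger.warning("subject: no subject truth available; stage skipped")
                _stage("subject", skipped=True, input=len(focused))
        except ValueError as exc:
            logger.warning("subject stage skipped: %s", exc)
            _stage("subject", skipped=True, input=len(focused), reason=str(exc))

    # -- popularity ----------------------------------------------------
    scores = []
    if cfg.popularity_enabled and len(focused) >= 2:
        scores = pop_mod.trending_scores(focused)
        _stage("popularity", input=len(focused), scored=len(scores))

    # -- sentiment -----------------------------------------------------
    sentiments = []
    if cfg.sentiment_enabled:
        sentiments = [sent_mod.score_article(
            a.title, a.body, lexicon,
            strong=cfg.sentiment_strong, neutral_band=cfg.sentiment_neutral_band)
            for a in focused]
        _stage("sentiment", input=len(focused), scored=len(sentiments))

    # -- report --------------------------------------------------------
    _write_reports(out, focused, geo_labels, subject_labels, scores, sentiments)
    manifest["generated_at"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def _write_reports(out: Path, focused, geo_labels, subject_labels, scores,
                   sentiments) -> None:
    if focused:
        start = min(a.published_at for a in focused)
        end = max(a.published_at for a in focused)
        series = trends_mod.daily_counts(focused, start, end)
        frame = series.to_frame()
        frame.to_csv(out / "daily_series.tsv", sep="\t", index=False)
        if len(series.counts) >= 2:
            fit = trends_mod.fit_trend(series)
            lines = ["year\tmean\tsd\tn_days\tpartial"]
            for ys in fit.yearly:
                sd = "" if ys.sd is None else f"{ys.sd:.4f}"
                lines.append(f"{ys.year}\t{ys.mean:.4f}\t{sd}\t{ys.n_days}\t{ys.partial}")
            lines.append(f"# OLS slope={fit.slope:.6g} intercept={fit.intercept:.6g}")
            (out / "yearly_stats.tsv").write_text("\n".join(lines) + "\n")
    if geo_labels:
        rows = geo_mod.geo_distribution(geo_labels, top_k=15)
        (out / "geo_distribution.tsv").write_text(
            "label\tpercent\n" + "".join(f"{l}\t{p:.2f}\n" for l, p in rows))
    if subject_labels:
        rows = subj_mod.subject_distribution(subject_labels, include_other=True)
        (out / "subject_distribution.tsv").write_text(
            "label\tpercent\n" + "".join(f"{l}\t{p:.2f}\n" for l, p in rows))
    if geo_labels and subject_labels:
        ct = trends_mod.crosstab_geo_subject(geo_labels, subject_labels, top_k=15)
        ct.to_csv(out / "crosstab.tsv", sep="\t")
    if scores and subject_labels:
        flags = [s.popular for s in scores]
        rows = pop_mod.popularity_by_subject(subject_labels, flags)
        (out / "popularity_by_subject.tsv").write_text(
            "subject\tprobability\tci_low\tci_high\tn\n" + "".join(
                f"{r.subject}\t{r.probability:.4f}\t{r.ci_low:.4f}\t{r.ci_high:.4f}\t{r.n}\n"
                for r in rows))
    if sentiments:
        summary = sent_mod.corpus_sentiment_summary(sentiments)
        (out / "sentiment_summary.tsv").write_text(
            "metric\tvalue\n" + "".join(f"{k}\t{v:.4f}\n" for k, v in summary.items()))
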