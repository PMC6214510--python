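# Methods note

This note records the statistical models, the parameter choices (with
defaults and rationale), and the assumptions behind each pipeline stage and
the synthetic-corpus evaluation. Symbols: an article has a title, a body of
`L` characters, a language tag, a publication timestamp (normalized to UTC),
a source-graph PageRank, and Twitter/Facebook share counts.

## 1. Keyword selection

Term tables are TSV files of `(language, term)` rows; the bundled English
table covers the `electronic cigarette(s)`, `e cig(s)`/`e-cig(s)`/`ecig(s)`,
`e cigarette(s)`/`e-cigarette(s)`/`ecigarette(s)`, `vape(s)`, `vaper(s)`,
`vaping` family (19 surface forms). Matching is case-insensitive,
longest-match-first, non-overlapping, with hyphen/space treated as
interchangeable inside multiword terms and `\w`-boundary guards on both
sides. For unsegmented scripts (zh, ja, th, km, lo, my) boundary guards are
disabled, since "word boundary" is undefined there. A language with no table
entries falls back to the English terms, because English ENDS brand terms
circulate verbatim in non-English text.

**Assumption:** keyword recall is treated as ~1 for articles genuinely about
ENDS; the downstream stages only ever see keyword-positive articles.

## 2. Relevance (primarily-focused) model

Binary logistic regression on four features per keyword-positive article:

- `n` — total mention count (title + body);
- `ln(1 + n)` — damped count, so ten mentions are not "ten times" one;
- `q = 1 − offset/L` — earliness of the first body mention (0 when the body
  has none);
- `t` — indicator of a title mention.

Fit with scikit-learn `LogisticRegression` unpenalized (`C = inf`,
lbfgs, `tol = 1e-6`); no regularization because the feature space is
4-dimensional and the editorial rule being learned (many mentions, early,
in the title ⇒ focused) is close to separable, so shrinkage would only bias
the decision boundary. Default decision threshold 0.5 (configurable).
Models persist as key-value TSV so trained weights are human-inspectable.

## 3. Geographic focus

Entities are matched against a gazetteer TSV mapping surface forms
(countries, capitals, major cities, country-linked organizations) to ISO
3166-1 alpha-3 codes; homonyms resolve first-entry-wins, so table order is
the disambiguation policy. Per-article tallies `c_k` by country decide:

- no entities → `UNK`;
- exactly one country mentioned → that country;
- `2·max_k c_k > Σ c_k` (strict majority of entity mentions) → that country;
- otherwise → `MUL` (multinational).

This is a deterministic rule, not a classifier: it has no parameters to
tune, is auditable per article, and its failure mode (metonymic mentions,
e.g. a US article quoting "Beijing") is visible in the entity tally.
Distribution reports exclude `UNK` from the denominator by default: articles
with no resolvable geography carry no information about *where* coverage
concentrates.

## 4. Subject classification

Nine categories motivated by the WHO MPOWER framework — age, bans, flavor,
industry, marketing, prevalence, prices, quitting, warnings — plus `other`.
Training labels come from two independent annotators per article,
adjudicated by the rule *disagreement ⇒ `other`*: a label two trained
annotators cannot agree on is not a reliable positive example of either
category, and `other` is the honest residual class.

The classifier is a unigram `CountVectorizer` plus one binary logistic
regression per category (one-vs-rest, default L2 penalty — here
regularization is needed, the vocabulary is much larger than the sample).
Prediction takes the argmax of per-category probabilities but **abstains to
`other`** when the best probability is below `margin = 0.5`: a one-vs-rest
probability below one half means the best category's own model considers
the article more likely *not* to be that category. Ties break
alphabetically for determinism.

`min_per_category` (default 10) rejects training sets too thin to estimate
a category's weights; the end-to-end pipeline lowers it to 2 because demo
corpora are small and a weak rare-category model is preferable to aborting
the run.

## 5. Popularity

Per-article trending score

`s_i = ( z(PageRank_i) + z(Twitter_i + Facebook_i) ) / 2`,

with `z(·)` the studentization `(x − mean)/sd`, `sd` computed with
`ddof = 1`. Equal weighting expresses no prior about whether network
authority or social sharing matters more; studentization is required because
the two inputs live on incomparable scales (PageRank ~10⁻⁴..1, shares
0..10⁴). A degenerate column (zero SD) studentizes to all-zeros with a
warning rather than raising, so a corpus with no share data still ranks by
PageRank. A `three_way` variant studentizes Twitter and Facebook separately
(three equal-weight z-columns) for corpora where the two platforms behave
differently.

Scores rank into deciles 1–10 (ties broken by score then id, deterministic);
**popular = decile ≥ 8**, i.e. the top ~30% of the corpus. Conditional
popularity by subject is estimated with a one-dummy logistic regression
(statsmodels `Logit`) per subject, reporting `P(popular | subject)` with a
Wald 95% CI. When a cell separates perfectly (all or none popular, either in
the subject or its complement), the saturated-model estimate is computed in
closed form instead of letting the optimizer diverge.

## 6. Sentiment

Lexicon-based, sentence-level, on a −1..1 scale. The bundled lexicon is a
TSV of unigrams with polarity weights ±1 (~30 positive, ~32 negative).
Sentences split on terminal punctuation with an abbreviation stop-list. A
sentence with matched positive mass `P` and negative mass `N` scores
`(P − N)/(P + N)`; sentences with no matches are skipped. The article score
is the **mean** over scored sentences (median available); mean is the
default because a single strongly worded sentence *should* move an
otherwise neutral article.

Categorization thresholds: `|score| ≥ 0.5` ⇒ strongly positive/negative,
`|score| ≤ 0.01` ⇒ neutral, otherwise somewhat positive/negative. A
"narrow" preset (±0.05 strong, ±0.01 neutral) suits mean-aggregated corpus
scores, where averaging over many sentences compresses the scale. The
sentence scorer is pluggable, so a model-based scorer can replace the
lexicon without touching aggregation or categorization.

## 7. Trends

Daily volume series are zero-filled over the full UTC date range (absence
of news is data). The linear trend is ordinary least squares of daily count
on day index (statsmodels OLS); per-year summaries report mean and SD
(`ddof = 1`, SD omitted for years with <2 observed days) with a flag for
partial years. The geography × subject crosstab reports row percentages for
the top-k nations plus an "all" margin row.

## 8. Synthetic corpus and evaluation design

The generator writes articles whose ground truth is realized *by
construction*, using four mutually disjoint token pools (keyword terms,
gazetteer entities, sentiment lexicon words, per-subject private
vocabulary), so one stage's signal cannot leak into another's:

- **Focus:** focused articles get ≥3 mentions, the first inside the opening
  20% of the body, usually plus a title mention; distractors get exactly one
  mention in the final 30% and none in the title. The 50/50
  focused/distractor split is the default stress mix.
- **Geography:** the focal country's entity tally leads any other by ≥2:1;
  `MUL` articles carry two countries with equal tallies. The country
  mixture is heavy-tailed (USA-dominant) with a 30% `MUL` mass.
- **Subject:** each category's articles draw from its private 6-token
  vocabulary; `other` articles use filler text only. Annotator pairs are
  simulated with a configurable disagreement rate (default 5% in the
  evaluation), and the classifier is scored against the *adjudicated*
  labels, not the latent truth — matching how a real model is evaluated.
- **Sentiment:** for a target score `t`, the generator mixes `n₀` neutral
  sentences with `m = ⌈n₀·|t|/(1−|t|)⌉` signed ±1 sentences, so the mean
  lands within ~0.04 of the target.
- **Popularity:** a latent per-article "buzz" variable drives both PageRank
  (uniform transform) and shares (log-normal quantile transform), drawn
  from top-30%/bottom-70% band mixtures per subject so that
  `P(popular | subject)` is controlled while the aggregate popular rate is
  balanced to 0.30 through the `other` category.
- **Volume:** in volume mode, daily counts are Poisson with per-year means
  (8, 36, 47, 51, 57, 75 per day over 2013–2018) and weekday weights, which
  the trend stage should recover.

Held-out evaluation (`endsmonitor.evaluation`, driven by
`scripts/acceptance.py`) measures micro-averaged precision — which equals
accuracy here, since every article receives a prediction — for relevance
(2,000 articles, 70/30 split), geography (2,000 articles, 10 countries +
`MUL`), and subject (3,000 articles, 5% annotator disagreement).

**Limitations.** Synthetic text is templated, not natural language: there
is no polysemy, no code-switching, no metonymy, and token pools are
disjoint by design. Precision measured here demonstrates that the
*implementations* recover the signals they model, under a generator that
realizes those signals cleanly; it is an upper bound on, not an estimate
of, performance on real news. The sentiment lexicon and gazetteer are
deliberately small, editable seed tables, not production resources.
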