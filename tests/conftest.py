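import datetime as dt

import pytest

from endsmonitor.corpus import NewsArticle
from endsmonitor.geo import Gazetteer
from endsmonitor.keywords import KeywordTable
from endsmonitor.sentiment import SentimentLexicon
from endsmonitor.synthetic import GeneratorConfig, generate_corpus


def make_article(id="a1", title="Title here", body="Body text.", **kw):
    defaults = dict(
        url=f"https://example.org/{id}",
        source="outlet",
        published_at=dt.date(2015, 6, 1),
        language="en",
        pagerank=5.0,
        twitter_shares=10,
        facebook_shares=20,
    )
    defaults.update(kw)
    return NewsArticle(id=id, title=title, body=body, **defaults)


@pytest.fixture(scope="session")
def keyword_table():
    return KeywordTable.bundled()


@pytest.fixture(scope="session")
def gazetteer():
    return Gazetteer.bundled()


@pytest.fixture(scope="session")
def lexicon():
    return SentimentLexicon.bundled()


@pytest.fixture(scope="session")
def small_synthetic():
    """A 400-article seeded corpus shared by read-only tests."""
    cfg = GeneratorConfig(n_articles=400, seed=7)
    articles, labels = generate_corpus(cfg)
    return cfg, articles, {l.article_id: l for l in labels}
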