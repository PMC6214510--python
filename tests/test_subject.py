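import numpy as np
import pytest

from endsmonitor.subject import (
    ALL_LABELS,
    OTHER,
    SUBJECT_CATEGORIES,
    SubjectModel,
    adjudicate_labels,
    classify_subject,
    subject_distribution,
    train_subject_classifier,
)
from endsmonitor.synthetic import SUBJECT_VOCAB
from .conftest import make_article


class TestAdjudication:
    def test_agreement_stands(self):
        assert adjudicate_labels("warnings", "warnings") == "warnings"

    def test_disagreement_is_other(self):
        assert adjudicate_labels("bans", "prices") == OTHER

    def test_other_pair(self):
        assert adjudicate_labels(OTHER, OTHER) == OTHER

    def test_symmetric(self):
        for a in ALL_LABELS:
            for b in ALL_LABELS:
                assert adjudicate_labels(a, b) == adjudicate_labels(b, a)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            adjudicate_labels("sports", "bans")


def _separable_corpus(n_per_cat=15, seed=0):
    """Each category's articles use that category's private vocabulary."""
    rng = np.random.default_rng(seed)
    articles, labels = [], []
    i = 0
    for cat in SUBJECT_CATEGORIES:
        vocab = SUBJECT_VOCAB[cat]
        for _ in range(n_per_cat):
            words = [vocab[k] for k in rng.integers(0, len(vocab), 12)]
            articles.append(make_article(
                id=f"{cat}-{i}", title=f"News about {words[0]}",
                body="The report discussed " + " ".join(words) + "."))
            labels.append(cat)
            i += 1
    return articles, labels


class TestTraining:
    def test_separable_held_out_accuracy(self):
        articles, labels = _separable_corpus(n_per_cat=30)
        idx = np.random.default_rng(1).permutation(len(articles))
        train = idx[: int(0.7 * len(idx))]
        test = idx[int(0.7 * len(idx)):]
        model = train_subject_classifier(
            [articles[i] for i in train], [labels[i] for i in train], seed=0)
        preds = [classify_subject(model, articles[i])[0] for i in test]
        assert all(p == labels[i] for p, i in zip(preds, test))

    def test_shuffled_labels_near_chance(self):
        articles, labels = _separable_corpus(n_per_cat=20)
        rng = np.random.default_rng(2)
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        model = train_subject_classifier(articles, shuffled, seed=0)
        preds = [classify_subject(model, a)[0] for a in articles]
        acc = np.mean([p == t for p, t in zip(preds, shuffled)])
        assert acc < 0.45  # far below the separable regime, near 1/9 + abstentions

    def test_same_seed_same_predictions(self):
        articles, labels = _separable_corpus(n_per_cat=12)
        m1 = train_subject_classifier(articles, labels, seed=9)
        m2 = train_subject_classifier(articles, labels, seed=9)
        probe, _ = _separable_corpus(n_per_cat=3, seed=5)
        assert [classify_subject(m1, a)[0] for a in probe] == \
               [classify_subject(m2, a)[0] for a in probe]

    def test_missing_category_rejected(self):
        articles, labels = _separable_corpus(n_per_cat=12)
        drop = [(a, l) for a, l in zip(articles, labels) if l != "flavor"]
        with pytest.raises(ValueError, match="flavor"):
            train_subject_classifier([a for a, _ in drop], [l for _, l in drop])

    def test_model_persistence_roundtrip(self, tmp_path):
        articles, labels = _separable_corpus(n_per_cat=12)
        model = train_subject_classifier(articles, labels, seed=0)
        p = tmp_path / "subject.json"
        model.save(p)
        back = SubjectModel.load(p)
        probe, _ = _separable_corpus(n_per_cat=2, seed=8)
        assert [classify_subject(back, a)[0] for a in probe] == \
               [classify_subject(model, a)[0] for a in probe]


@pytest.fixture(scope="module")
def model():
    articles, labels = _separable_corpus(n_per_cat=20)
    return train_subject_classifier(articles, labels, seed=0)


class TestClassification:

    def test_out_of_vocabulary_is_other(self, model):
        art = make_article(body="zzz qqq completely unrelated nonsense tokens")
        label, scores = classify_subject(model, art)
        assert label == OTHER

    def test_saturated_category_vocabulary(self, model):
        body = " ".join(SUBJECT_VOCAB["prices"] * 4)
        label, scores = classify_subject(model, make_article(body=body))
        assert label == "prices"
        assert scores["prices"] == max(scores.values())

    def test_scores_cover_all_categories(self, model):
        _, scores = classify_subject(model, make_article(body="tax levy"))
        assert set(scores) == set(SUBJECT_CATEGORIES)

    def test_tie_breaks_alphabetically(self):
        model = SubjectModel(
            vocabulary={"tok": 0},
            intercepts={c: 5.0 for c in SUBJECT_CATEGORIES},
            weights={c: np.zeros(1) for c in SUBJECT_CATEGORIES},
        )
        label, _ = classify_subject(model, make_article(body="tok"))
        assert label == "age"  # alphabetically first category

    def test_unfitted_model_rejected(self):
        model = SubjectModel(vocabulary={}, intercepts={}, weights={})
        with pytest.raises(ValueError):
            classify_subject(model, make_article())


class TestDistribution:
    def test_percentages_with_other_denominator(self):
        labels = ["warnings"] * 18 + ["bans"] * 13 + [OTHER] * 69
        dist = dict(subject_distribution(labels, include_other=False))
        assert dist["warnings"] == pytest.approx(18.0)
        assert dist["bans"] == pytest.approx(13.0)
        assert OTHER not in dist
        assert sum(dist.values()) < 100.0  # "other" mass hidden, not re-normalized

    def test_all_other_excluded_is_empty(self):
        assert subject_distribution([OTHER] * 4, include_other=False) == []

    def test_sums_to_hundred_with_other(self):
        rng = np.random.default_rng(3)
        labels = [str(l) for l in rng.choice(list(ALL_LABELS), 1000)]
        dist = subject_distribution(labels, include_other=True)
        assert sum(p for _, p in dist) == pytest.approx(100.0)
        for lab, pct in dist:
            assert pct == pytest.approx(100.0 * labels.count(lab) / 1000)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subject_distribution([])
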