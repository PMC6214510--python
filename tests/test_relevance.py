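import math

import numpy as np
import pytest

from endsmonitor.keywords import MentionSpan
from endsmonitor.relevance import (
    RelevanceFeatures,
    RelevanceModel,
    evaluate_precision,
    extract_relevance_features,
    fit_relevance_weights,
    score_relevance,
)
from .conftest import make_article


def feats(count=1, first=0.5, title=0):
    return RelevanceFeatures(
        mention_count=count, log_mention_count=math.log1p(count),
        first_position=first, title_hit=title)


class TestFeatureExtraction:
    def test_title_only_mention(self):
        art = make_article(body="x" * 50, title="Vaping up")
        spans = [MentionSpan("vaping", 0, 6, "title")]
        f = extract_relevance_features(art, spans)
        assert f.first_position == 0.0
        assert f.title_hit == 1
        assert f.mention_count == 1

    def test_mention_at_body_start(self):
        art = make_article(body="v" * 100)
        f = extract_relevance_features(art, [MentionSpan("vape", 0, 4, "body")])
        assert f.first_position == 1.0

    def test_two_mentions_mid_body(self):
        art = make_article(body="x" * 200)
        spans = [MentionSpan("vape", 100, 104, "body"),
                 MentionSpan("vape", 150, 154, "body")]
        f = extract_relevance_features(art, spans)
        assert f.first_position == pytest.approx(0.5)
        assert f.mention_count == 2
        assert f.log_mention_count == pytest.approx(math.log(3))
        assert f.title_hit == 0

    def test_empty_body_with_body_spans_is_error(self):
        art = make_article(body="")
        with pytest.raises(ValueError):
            extract_relevance_features(art, [MentionSpan("vape", 0, 4, "body")])


def _separated_training_set():
    focused = [feats(count=10, first=0.9, title=1) for _ in range(20)]
    distract = [feats(count=1, first=0.05, title=0) for _ in range(20)]
    return focused + distract, [True] * 20 + [False] * 20


class TestFit:
    def test_separable_set_classified_perfectly(self):
        X, y = _separated_training_set()
        model = fit_relevance_weights(X, y)
        preds = [score_relevance(model, f)[1] for f in X]
        assert preds == y

    def test_distractor_features_rejected(self):
        X, y = _separated_training_set()
        model = fit_relevance_weights(X, y)
        prob, focused = score_relevance(model, feats(count=1, first=0.05, title=0))
        assert not focused

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = [feats(count=int(c), first=float(p), title=int(t))
             for c, p, t in zip(rng.integers(1, 10, 400),
                                rng.uniform(0, 1, 400),
                                rng.integers(0, 2, 400))]
        y = list(rng.random(400) < 0.5)
        model = fit_relevance_weights(X, y)
        preds = [score_relevance(model, f)[1] for f in X]
        acc = np.mean([p == t for p, t in zip(preds, y)])
        majority = max(np.mean(y), 1 - np.mean(y))
        assert abs(acc - majority) < 0.1

    def test_duplication_leaves_weights_unchanged(self):
        # the likelihood is invariant to uniform duplication of examples
        rng = np.random.default_rng(1)
        X = [feats(count=int(c), first=float(p)) for c, p in
             zip(rng.integers(1, 8, 60), rng.uniform(0, 1, 60))]
        y = [c > 4 for c in (f.mention_count for f in X)]
        w1 = fit_relevance_weights(X, y).weights
        w2 = fit_relevance_weights(X + X, y + y).weights
        assert np.allclose(w1, w2, atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_relevance_weights([feats(), feats()], [True, True])

    def test_order_free_refit(self):
        X, y = _separated_training_set()
        model_a = fit_relevance_weights(X, y)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(X))
        model_b = fit_relevance_weights([X[i] for i in perm], [y[i] for i in perm])
        probe = [feats(count=c, first=p) for c in (1, 5, 10) for p in (0.1, 0.9)]
        pa = [score_relevance(model_a, f)[1] for f in probe]
        pb = [score_relevance(model_b, f)[1] for f in probe]
        assert pa == pb


class TestScore:
    def test_zero_weights_give_half(self):
        model = RelevanceModel(weights=np.zeros(4))
        prob, _ = score_relevance(model, feats(count=7, first=0.3, title=1))
        assert prob == pytest.approx(0.5)

    def test_monotone_in_mention_count(self):
        model = RelevanceModel(weights=np.array([-1.0, 2.0, 0.5, 0.2]))
        probs = [score_relevance(model, feats(count=c))[0] for c in range(1, 30)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_threshold_sweep_non_increasing(self):
        X, y = _separated_training_set()
        model = fit_relevance_weights(X, y)
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = RelevanceModel(weights=model.weights, threshold=thr)
            counts.append(sum(score_relevance(m, f)[1] for f in X))
        assert counts == sorted(counts, reverse=True)

    def test_model_persistence_roundtrip(self, tmp_path):
        X, y = _separated_training_set()
        model = fit_relevance_weights(X, y, threshold=0.4)
        p = tmp_path / "model.tsv"
        model.save(p)
        back = RelevanceModel.load(p)
        assert np.allclose(back.weights, model.weights)
        assert back.threshold == 0.4


class TestPrecision:
    def test_all_correct(self):
        rep = evaluate_precision([True] * 10, [True] * 10)
        assert rep.precision == 1.0

    def test_mixed_tally(self):
        predicted = [True] * 100
        truth = [True] * 81 + [False] * 19
        rep = evaluate_precision(predicted, truth)
        assert rep.true_positives == 81
        assert rep.false_positives == 19
        assert rep.precision == pytest.approx(0.81)

    def test_no_positive_predictions_undefined(self):
        rep = evaluate_precision([False] * 5, [True] * 5)
        assert rep.precision is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_precision([True], [True, False])
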