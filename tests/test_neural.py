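"""Embeddings, encoders, backprop correctness and matcher training."""

import numpy as np
import pytest

from pwmap import neural as nn
from pwmap.training_data import TrainingSet
from pwmap.types import TrainingPair


@pytest.fixture
def store() -> nn.EmbeddingStore:
    rng = np.random.default_rng(0)
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    return nn.EmbeddingStore(
        dim=8, vectors={t: rng.normal(size=8) for t in vocab}
    )


class TestEmbeddingStore:
    def test_unknown_token_is_zero_vector(self, store):
        assert np.array_equal(store["nope"], np.zeros(8))

    def test_word_vector_file_round_trip(self, store, tmp_path):
        path = tmp_path / "vecs.txt"
        nn.write_word_vectors(store, path)
        loaded = nn.read_word_vectors(path)
        assert loaded.dim == store.dim
        for token, vec in store.vectors.items():
            assert np.allclose(loaded[token], vec)

    def test_concat_stores(self, store):
        combined = nn.concat_stores(store, store)
        assert combined.dim == 16
        assert np.allclose(combined["alpha"][:8], store["alpha"])

    def test_inconsistent_length_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("a 1.0 2.0\nb 1.0\n")
        with pytest.raises(ValueError):
            nn.read_word_vectors(path)


class TestNameBag:
    def test_single_token_identity(self, store):
        assert np.array_equal(nn.embed_name_bag(["alpha"], store), store["alpha"])

    def test_order_invariance(self, store):
        a = nn.embed_name_bag(["alpha", "beta", "gamma"], store)
        b = nn.embed_name_bag(["gamma", "alpha", "beta"], store)
        assert np.allclose(a, b)

    def test_cancellation(self):
        s = nn.EmbeddingStore(dim=3, vectors={"p": np.ones(3), "m": -np.ones(3)})
        assert np.allclose(nn.embed_name_bag(["p", "m"], s), np.zeros(3))

    def test_empty_input(self, store):
        assert np.array_equal(nn.embed_name_bag([], store), np.zeros(8))


class TestDefinitionEncoder:
    def test_empty_definition_is_zero_vector(self, store):
        enc = nn.DefinitionMatcher(store, hidden=4, seed=0)
        assert np.array_equal(enc.encode(""), np.zeros(8))

    def test_deterministic(self, store):
        enc = nn.DefinitionMatcher(store, hidden=4, seed=0)
        a = enc.encode("alpha beta gamma")
        b = enc.encode("alpha beta gamma")
        assert np.array_equal(a, b)

    def test_order_sensitive(self, store):
        enc = nn.DefinitionMatcher(store, hidden=4, seed=0)
        fwd = enc.encode("alpha beta gamma delta")
        rev = enc.encode("delta gamma beta alpha")
        assert not np.allclose(fwd, rev)

    def test_padding_does_not_change_encoding(self, store):
        # encoding of a text must not depend on the longest batch-mate
        enc = nn.DefinitionMatcher(store, hidden=4, seed=0)
        alone = enc.encode_batch(["alpha beta"])[0]
        padded = enc.encode_batch(["alpha beta", "alpha beta gamma delta epsilon"])[0]
        assert np.allclose(alone, padded)

    def test_encode_definition_wrapper(self, store):
        enc = nn.DefinitionMatcher(store, hidden=4, seed=0)
        via_tokens = nn.encode_definition(["alpha", "beta"], store, enc)
        assert np.allclose(via_tokens, enc.encode("alpha beta"))


class TestScorePair:
    def test_scores_strictly_inside_unit_interval(self, store):
        for matcher in (nn.NameMatcher(store, seed=1),
                        nn.DefinitionMatcher(store, hidden=4, seed=1)):
            s = nn.score_pair("alpha beta", "gamma", matcher)
            assert 0.0 < s < 1.0

    def test_unknown_tokens_give_constant_score(self, store):
        matcher = nn.NameMatcher(store, seed=1)
        s1 = matcher.score("qqq www", "rrr")
        s2 = matcher.score("xxx", "yyy zzz uuu")
        assert s1 == pytest.approx(s2)

    def test_name_matcher_word_order_invariant(self, store):
        matcher = nn.NameMatcher(store, seed=1)
        assert matcher.score("alpha beta", "gamma delta") == pytest.approx(
            matcher.score("beta alpha", "delta gamma")
        )


def numeric_grad(matcher, texts_a, texts_b, y, param, index, eps=1e-6):
    def loss_at(value):
        old = param[index]
        param[index] = value
        logits = matcher.logits(texts_a, texts_b)
        loss, _ = nn._bce_and_grad(logits, y)
        param[index] = old
        return loss

    base = param[index]
    return (loss_at(base + eps) - loss_at(base - eps)) / (2 * eps)


@pytest.mark.parametrize("kind", ["name", "definition"])
def test_backprop_matches_finite_differences(store, kind):
    """Analytic gradients of both matchers agree with central differences."""
    if kind == "name":
        matcher = nn.NameMatcher(store, decision_hidden=5, seed=2)
    else:
        matcher = nn.DefinitionMatcher(store, hidden=3, decision_hidden=5, seed=2)
    texts_a = ["alpha beta gamma", "delta", "epsilon zeta alpha"]
    texts_b = ["gamma beta", "alpha delta epsilon", "zeta"]
    y = np.array([1.0, 0.0, 1.0])

    logits = matcher.logits(texts_a, texts_b)
    _, dlogits = nn._bce_and_grad(logits, y)
    matcher.backward(dlogits)
    analytic = [g.copy() for g in matcher.grads()]

    rng = np.random.default_rng(0)
    for param, grad in zip(matcher.params(), analytic):
        flat_param = param.reshape(-1)
        flat_grad = grad.reshape(-1)
        for index in rng.choice(flat_param.size, size=min(6, flat_param.size), replace=False):
            num = numeric_grad(matcher, texts_a, texts_b, y, flat_param, index)
            assert num == pytest.approx(flat_grad[index], abs=1e-6, rel=1e-4)


def balanced_pairs(n: int, seed: int = 0) -> TrainingSet:
    """Separable name pairs: positives share all tokens, negatives none."""
    rng = np.random.default_rng(seed)
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    pairs = []
    for i in range(n // 2):
        words = list(rng.choice(vocab[:3], size=2, replace=False))
        other = list(rng.choice(vocab[3:], size=2, replace=False))
        text = " ".join(words)
        pairs.append(TrainingPair(f"P{i}", f"C{i}", text, text, "positive", "t",
                                  a_def=text, b_def=text))
        pairs.append(TrainingPair(f"P{i}", f"X{i}", text, " ".join(other),
                                  "negative", "t", a_def=text, b_def=" ".join(other)))
    return TrainingSet(pairs)


class TestSplitTrainDev:
    def test_stratified_sizes(self):
        ts = balanced_pairs(100)
        train, dev = nn.split_train_dev(ts, dev_frac=0.10, seed=0)
        assert len(dev.pairs) == 10
        assert len([p for p in dev.pairs if p.label == "positive"]) == 5
        assert set(p.pair for p in train.pairs).isdisjoint(
            p.pair for p in dev.pairs
        )

    def test_seed_reproducible(self):
        ts = balanced_pairs(40)
        a = nn.split_train_dev(ts, seed=3)
        b = nn.split_train_dev(ts, seed=3)
        assert a[0].pairs == b[0].pairs and a[1].pairs == b[1].pairs

    def test_half_split_on_four_pairs(self):
        ts = balanced_pairs(4)
        train, dev = nn.split_train_dev(ts, dev_frac=0.5, seed=0)
        assert len(train.pairs) == 2 and len(dev.pairs) == 2

    def test_tiny_label_class_rejected(self):
        ts = TrainingSet(balanced_pairs(8).positives
                         + balanced_pairs(4).negatives[:1])
        with pytest.raises(ValueError):
            nn.split_train_dev(ts, seed=0)


class TestTrainMatcher:
    def test_loss_decreases_and_snapshot_is_argmax(self, store):
        ts = balanced_pairs(60, seed=1)
        train, dev = nn.split_train_dev(ts, 0.2, seed=1)
        matcher = nn.NameMatcher(store, decision_hidden=16, seed=1)
        matcher, history = nn.train_matcher(matcher, train, dev, epochs=15, seed=1)
        assert history[-1].train_loss <= history[0].train_loss
        best_recall = max(h.dev_recall for h in history)
        da, db_, dy = nn.pair_texts(dev.pairs, "name")
        final_recall = nn._recall(matcher.score_batch(da, db_), dy, matcher.threshold)
        assert final_recall == pytest.approx(best_recall)

    def test_training_is_seed_reproducible(self, store):
        ts = balanced_pairs(40, seed=2)
        train, dev = nn.split_train_dev(ts, 0.2, seed=2)
        outputs = []
        for _ in range(2):
            matcher = nn.NameMatcher(store, decision_hidden=8, seed=5)
            matcher, _ = nn.train_matcher(matcher, train, dev, epochs=5, seed=5)
            outputs.append(matcher.score("alpha beta", "beta alpha"))
        assert outputs[0] == outputs[1]

    def test_definition_matcher_learns_separable_pairs(self, store):
        ts = balanced_pairs(60, seed=3)
        train, dev = nn.split_train_dev(ts, 0.2, seed=3)
        matcher = nn.DefinitionMatcher(store, hidden=8, decision_hidden=16, seed=3)
        matcher, _ = nn.train_matcher(matcher, train, dev, epochs=25, seed=3)
        ta, tb, ty = nn.pair_texts(train.pairs, "definition")
        scores = matcher.score_batch(ta, tb)
        assert scores[ty == 1].mean() > scores[ty == 0].mean()

    def test_single_label_dev_rejected(self, store):
        ts = balanced_pairs(20)
        train, _ = nn.split_train_dev(ts, 0.2, seed=0)
        dev = TrainingSet(ts.positives[:3])
        matcher = nn.NameMatcher(store, seed=0)
        with pytest.raises(ValueError):
            nn.train_matcher(matcher, train, dev, epochs=2)


class TestMatcherSerialization:
    def test_save_load_round_trip(self, store, tmp_path):
        for matcher in (nn.NameMatcher(store, decision_hidden=8, seed=4),
                        nn.DefinitionMatcher(store, hidden=3, decision_hidden=8, seed=4)):
            path = tmp_path / f"{matcher.kind}.npz"
            nn.save_matcher(matcher, path)
            loaded = nn.load_matcher(path, store)
            assert loaded.score("alpha beta", "gamma") == pytest.approx(
                matcher.score("alpha beta", "gamma")
            )
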