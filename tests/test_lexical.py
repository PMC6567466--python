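"""Tokenisation, idf weighting, weighted Jaccard and candidate blocking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pwmap import lexical as lx
from pwmap.types import PathwayRecord

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

token_sets = st.frozensets(
    st.sampled_from(["apoptotic", "pathway", "signaling", "cell", "death", "lipid"]),
    max_size=6,
)


def flat_idf(value: float = 1.0, doc_count: int = 10) -> lx.IdfTable:
    tokens = ["apoptotic", "pathway", "signaling", "cell", "death", "lipid"]
    return lx.IdfTable(doc_count=doc_count, idf={t: value for t in tokens})


class TestTokenize:
    @pytest.mark.parametrize(
        "text,sizes,expected",
        [
            ("acid", {3}, {"acid", "3#aci", "3#cid"}),
            ("", {3, 4, 5}, set()),
            ("Fatty-acid", set(), {"fatty", "acid"}),
            ("ab", {3}, {"ab"}),  # word shorter than n: no n-grams
        ],
    )
    def test_examples(self, text, sizes, expected):
        assert lx.tokenize(text, sizes) == expected

    def test_ngram_namespacing_prevents_collisions(self):
        # the word "aci" and the 3-gram of "acid" must remain distinct tokens
        tokens = lx.tokenize("aci acid", {3})
        assert "aci" in tokens and "3#aci" in tokens


class TestIdf:
    def test_token_in_every_document_gets_one(self):
        idf = lx.build_idf(["common"] * 10, ())
        assert idf["common"] == pytest.approx(1.0)

    def test_rare_token_formula(self):
        idf = lx.build_idf(["rare"] + ["filler"] * 9, ())
        assert idf["rare"] == pytest.approx(math.log(10) + 1)

    def test_monotone_in_document_frequency(self):
        corpus = ["a b"] * 2 + ["b c"] * 3 + ["c"] * 5
        idf = lx.build_idf(corpus, ())
        assert idf["a"] > idf["b"] > idf["c"]

    def test_unknown_token_gets_maximum(self):
        idf = lx.build_idf(["x"] * 10, ())
        assert idf["never-seen"] == pytest.approx(math.log(10) + 1)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            lx.build_idf([], ())


class TestWeightedJaccard:
    def test_identical_sets(self):
        a = frozenset({"apoptotic", "pathway"})
        assert lx.weighted_jaccard(a, a, flat_idf()) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert lx.weighted_jaccard(
            frozenset({"apoptotic"}), frozenset({"lipid"}), flat_idf()
        ) == 0.0

    def test_hand_evaluated_example(self):
        idf = lx.IdfTable(
            doc_count=10, idf={"apoptotic": 2.0, "pathway": 0.5, "signaling": 1.0}
        )
        a = frozenset({"apoptotic", "pathway"})
        b = frozenset({"pathway", "signaling"})
        assert lx.weighted_jaccard(a, b, idf) == pytest.approx(0.5 / 3.5)

    def test_empty_union_is_zero(self):
        assert lx.weighted_jaccard(frozenset(), frozenset(), flat_idf()) == 0.0

    @given(a=token_sets, b=token_sets)
    def test_constant_idf_reduces_to_unweighted_jaccard(self, a, b):
        got = lx.weighted_jaccard(a, b, flat_idf(3.7))
        expected = len(a & b) / len(a | b) if a | b else 0.0
        assert got == pytest.approx(expected, abs=1e-12)

    @given(a=token_sets, b=token_sets)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        idf = lx.build_idf(["apoptotic pathway", "signaling cell death", "lipid"], ())
        j = lx.weighted_jaccard(a, b, idf)
        assert j == lx.weighted_jaccard(b, a, idf)
        assert 0.0 <= j <= 1.0
        if a or b:
            assert (j == pytest.approx(1.0)) == (a == b)


class TestOverlapScore:
    def test_disjoint(self):
        assert lx.lexical_overlap_score(
            frozenset({"apoptotic"}), frozenset({"lipid"}), flat_idf()
        ) == 0.0

    def test_sum_identity(self):
        idf = lx.IdfTable(doc_count=10, idf={"x": 1.0, "y": 2.0})
        s = frozenset({"x", "y"})
        assert lx.lexical_overlap_score(s, s, idf) == pytest.approx(3.0)

    def test_single_shared_token(self):
        idf = lx.IdfTable(doc_count=10, idf={"pathway": 0.5, "a": 2.0, "b": 2.0})
        assert lx.lexical_overlap_score(
            frozenset({"pathway", "a"}), frozenset({"pathway", "b"}), idf
        ) == pytest.approx(0.5)


def brute_force_ranking(query, targets, idf, k):
    scored = [
        (tid, lx.lexical_overlap_score(query, tokens, idf))
        for tid, tokens in targets.items()
    ]
    scored = [(tid, s) for tid, s in scored if s > 0]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored[:k]


class TestSelectCandidates:
    def make_instance(self, seed, n_targets=50):
        import numpy as np

        rng = np.random.default_rng(seed)
        vocab = [f"tok{i}" for i in range(30)]
        targets = {
            f"T{i:03d}": frozenset(
                rng.choice(vocab, size=rng.integers(1, 6), replace=False)
            )
            for i in range(n_targets)
        }
        query = frozenset(rng.choice(vocab, size=4, replace=False))
        idf = lx.build_idf([" ".join(t) for t in targets.values()], ())
        return query, targets, idf

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        query, targets, idf = self.make_instance(seed)
        assert lx.select_candidates(query, targets, idf, k=20) == brute_force_ranking(
            query, targets, idf, 20
        )

    def test_only_overlapping_targets_returned(self):
        targets = {
            "T1": frozenset({"shared", "x"}),
            "T2": frozenset({"shared"}),
            "T3": frozenset({"unrelated"}),
        }
        idf = lx.build_idf(["shared x", "shared", "unrelated"], ())
        result = lx.select_candidates(frozenset({"shared", "q"}), targets, idf, k=20)
        assert [tid for tid, _ in result] == ["T1", "T2"] or [
            tid for tid, _ in result
        ] == ["T2", "T1"]
        assert "T3" not in dict(result)

    def test_disjoint_query_yields_empty(self):
        targets = {"T1": frozenset({"a"})}
        idf = lx.build_idf(["a"], ())
        assert lx.select_candidates(frozenset({"zzz"}), targets, idf) == []

    def test_truncation_keeps_top_k(self):
        query, targets, idf = self.make_instance(3, n_targets=80)
        full = brute_force_ranking(query, targets, idf, k=10**9)
        got = lx.select_candidates(query, targets, idf, k=20)
        if len(full) > 20:
            assert len(got) == 20
            assert min(s for _, s in got) >= full[20][1]


class TestBowPredict:
    def setup_method(self):
        self.idf = lx.IdfTable(
            doc_count=10, idf={t: 1.0 for t in "abcdefgh"}
        )
        self.pathway = PathwayRecord("P:1", "db", ["whatever"])

    def test_threshold_filters(self):
        tokens = frozenset({"a", "b", "c", "d", "e"})
        classes = {
            "C1": frozenset({"a", "b", "c"}),  # J = 3/5 = 0.6
            "C2": frozenset({"a", "f", "g", "h"}),  # J = 1/8
            "C3": frozenset({"f"}),  # J = 0
        }
        preds = lx.bow_predict(self.pathway, tokens, classes, self.idf, 0.5)
        assert [(p.class_id, p.rank) for p in preds] == [("C1", 1)]

    def test_threshold_one_keeps_exact_matches_only(self):
        tokens = frozenset({"a", "b"})
        classes = {"C1": frozenset({"a", "b"}), "C2": frozenset({"a"})}
        preds = lx.bow_predict(self.pathway, tokens, classes, self.idf, 1.0)
        assert [p.class_id for p in preds] == ["C1"]

    def test_threshold_zero_emits_all_overlapping(self):
        tokens = frozenset({"a"})
        classes = {"C1": frozenset({"a", "b"}), "C2": frozenset({"c"})}
        preds = lx.bow_predict(self.pathway, tokens, classes, self.idf, 0.0)
        assert [p.class_id for p in preds] == ["C1"]


class TestFitBowThreshold:
    def test_clean_separation_returns_smallest_winner(self):
        pairs = [(0.9, "positive")] * 3 + [(0.1, "negative")] * 3
        assert lx.fit_bow_threshold(pairs) == pytest.approx(0.11)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            lx.fit_bow_threshold([(0.9, "positive"), (0.8, "positive")])

    def test_returned_threshold_is_grid_optimal(self):
        pairs = [
            (0.95, "positive"), (0.7, "positive"), (0.65, "negative"),
            (0.6, "positive"), (0.4, "negative"), (0.2, "negative"),
            (0.55, "positive"), (0.5, "negative"),
        ]
        best = lx.fit_bow_threshold(pairs)

        def f1(threshold):
            tp = sum(1 for s, l in pairs if s >= threshold and l == "positive")
            fp = sum(1 for s, l in pairs if s >= threshold and l == "negative")
            fn = sum(1 for s, l in pairs if s < threshold and l == "positive")
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            return 2 * p * r / (p + r) if p + r else 0.0

        assert all(f1(best) >= f1(t / 100) for t in range(1, 100))
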