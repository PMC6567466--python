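"""Iterative bootstrapping of training pairs with a lexical logistic model.

A logistic-regression classifier over five cheap lexical-similarity features
is trained on the current labelled pairs, run over every (pathway, candidate
class) pair produced by the top-k blocking step, and the extreme tails of the
score distribution — the top and bottom 0.25% by default — are appended as
new positive and negative training pairs.  Ten such rounds adapt the
training table to the target database without any manual labelling.

Features (all symmetric, all in [0, 1]):

* normalised absolute word-token count difference, ``|p - q| / max(p, q, 1)``
* word-token Jaccard index
* character n-gram Jaccard index for n = 3, 4, 5 (within-word n-grams)
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, astuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .lexical import (
    DEFAULT_TOP_K,
    CandidateSelector,
    IdfTable,
    char_ngrams,
    word_tokens,
)
from .types import (
    NEGATIVE,
    POSITIVE,
    OntologyClass,
    PathwayRecord,
    TrainingPair,
)
from .training_data import TrainingSet, _pair_from_mapping
from .types import MappingRecord

logger = logging.getLogger(__name__)

BOOTSTRAP_FRACTION = 0.0025
BOOTSTRAP_ITERATIONS = 10


@dataclass(frozen=True)
class LexicalFeatureVector:
    token_count_diff: float
    word_jaccard: float
    char_jaccard_3: float
    char_jaccard_4: float
    char_jaccard_5: float

    def as_array(self) -> np.ndarray:
        return np.asarray(astuple(self), dtype=float)


def _jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    if not union:
        return 1.0  # two empty texts are identical
    return len(a & b) / len(union)


def _ngram_set(words: Sequence[str], n: int) -> set[str]:
    return {g for w in words for g in char_ngrams(w, n)}


def lexical_features(text_a: str, text_b: str) -> LexicalFeatureVector:
    """The five unweighted lexical-similarity features of a text pair."""
    words_a, words_b = word_tokens(text_a), word_tokens(text_b)
    p, q = len(words_a), len(words_b)
    set_a, set_b = set(words_a), set(words_b)
    return LexicalFeatureVector(
        token_count_diff=abs(p - q) / max(p, q, 1),
        word_jaccard=_jaccard(set_a, set_b),
        char_jaccard_3=_jaccard(_ngram_set(words_a, 3), _ngram_set(words_b, 3)),
        char_jaccard_4=_jaccard(_ngram_set(words_a, 4), _ngram_set(words_b, 4)),
        char_jaccard_5=_jaccard(_ngram_set(words_a, 5), _ngram_set(words_b, 5)),
    )


def _pair_text_a(pair: TrainingPair) -> str:
    return " ".join(pair.a_names)


def _pair_text_b(pair: TrainingPair) -> str:
    return " ".join(pair.b_names)


def _feature_matrix(pairs: Sequence[TrainingPair]) -> np.ndarray:
    return np.vstack(
        [lexical_features(_pair_text_a(p), _pair_text_b(p)).as_array() for p in pairs]
    )


def fit_bootstrap_model(training: TrainingSet, seed: int = 0) -> LogisticRegression:
    """Fit the 5-feature logistic model on the current training pairs."""
    if not training.pairs:
        raise ValueError("cannot fit on an empty training set")
    y = np.array([1 if p.label == POSITIVE else 0 for p in training.pairs])
    if y.min() == y.max():
        raise ValueError("training set must contain both labels")
    x = _feature_matrix(training.pairs)
    model = LogisticRegression(random_state=seed, max_iter=1000)
    model.fit(x, y)
    return model


CandidateCache = tuple[list[tuple[str, str]], np.ndarray]


def candidate_pair_features(
    pathways: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
    selector: CandidateSelector,
    pathway_tokens: Mapping[str, frozenset[str]],
    k: int = DEFAULT_TOP_K,
) -> CandidateCache:
    """All (pathway, top-k candidate) pairs with their feature matrix.

    Candidate lists and lexical features do not depend on the training set,
    so one cache serves every bootstrap iteration.
    """
    pairs: list[tuple[str, str]] = []
    feats: list[np.ndarray] = []
    for pathway_id in sorted(pathways):
        text_a = " ".join(pathways[pathway_id].names)
        for class_id, _score in selector.select(pathway_tokens[pathway_id], k=k):
            pairs.append((pathway_id, class_id))
            feats.append(
                lexical_features(text_a, " ".join(ontology[class_id].names)).as_array()
            )
    matrix = np.vstack(feats) if feats else np.zeros((0, 5))
    return pairs, matrix


def bootstrap_round(
    model: LogisticRegression,
    pathways: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
    selector: CandidateSelector,
    pathway_tokens: Mapping[str, frozenset[str]],
    existing: TrainingSet,
    frac: float = BOOTSTRAP_FRACTION,
    k: int = DEFAULT_TOP_K,
    cache: CandidateCache | None = None,
) -> tuple[list[TrainingPair], list[TrainingPair]]:
    """Score every (pathway, top-k candidate) pair and harvest the tails.

    The pool is the set of scored candidate pairs not already in ``existing``;
    the ceil(frac * pool) highest-scoring become positives and the same number
    of lowest-scoring become negatives.  Ceiling (not floor) so that small
    corpora still bootstrap.
    """
    if frac <= 0:
        return [], []
    if cache is None:
        cache = candidate_pair_features(pathways, ontology, selector, pathway_tokens, k)
    all_pairs, all_feats = cache
    existing_ids = existing.pair_ids()
    keep = [i for i, pair in enumerate(all_pairs) if pair not in existing_ids]
    if not keep:
        return [], []
    pool = [all_pairs[i] for i in keep]
    probs = model.predict_proba(all_feats[keep])[:, 1]
    take = math.ceil(frac * len(pool))
    # Deterministic order: by probability, ties by pair id.
    order = sorted(range(len(pool)), key=lambda i: (-probs[i], pool[i]))
    top = [pool[i] for i in order[:take]]
    bottom = [pool[i] for i in order[len(order) - take :]]

    def to_pairs(ids: list[tuple[str, str]], label: str) -> list[TrainingPair]:
        return [
            _pair_from_mapping(
                MappingRecord(pid, cid, label, source="bootstrap"), pathways, ontology
            )
            for pid, cid in ids
        ]

    positives = to_pairs(top, POSITIVE)
    negatives = to_pairs([p for p in bottom if p not in set(top)], NEGATIVE)
    return positives, negatives


def run_bootstrap(
    initial: TrainingSet,
    pathways: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
    selector: CandidateSelector,
    pathway_tokens: Mapping[str, frozenset[str]],
    iters: int = BOOTSTRAP_ITERATIONS,
    frac: float = BOOTSTRAP_FRACTION,
    k: int = DEFAULT_TOP_K,
    seed: int = 0,
) -> TrainingSet:
    """Run ``iters`` rounds of refit-score-append on a copy of ``initial``.

    Each round refits the logistic model on the cumulative training set, so
    harvested pairs influence subsequent rounds.  Per-iteration counts are
    logged.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    training = TrainingSet(list(initial.pairs))
    cache = candidate_pair_features(pathways, ontology, selector, pathway_tokens, k)
    for iteration in range(1, iters + 1):
        model = fit_bootstrap_model(training, seed=seed)
        new_pos, new_neg = bootstrap_round(
            model, pathways, ontology, selector, pathway_tokens, training, frac, k,
            cache=cache,
        )
        training.extend(new_pos)
        training.extend(new_neg)
        logger.info(
            "bootstrap iteration %d: +%d positives, +%d negatives (total %d)",
            iteration,
            len(new_pos),
            len(new_neg),
            len(training.pairs),
        )
    return training
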