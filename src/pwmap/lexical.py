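"""Lexical similarity: tokenisation, idf weighting, the idf-weighted Jaccard
index, top-k candidate blocking, and the bag-of-words baseline predictor.

The weighted Jaccard between token sets ``A`` and ``B`` is

    J = sum_{t in A&B} idf(t) / sum_{t in A|B} idf(t)

with ``idf(t) = ln(N/df) + 1`` over the corpus of entity string
representations.  The smoothed ``+1`` keeps every weight strictly positive so
the denominator never vanishes for a non-empty union.

Candidate selection ranks ontology classes by the *overlap score* — the sum
of idf weights of the tokens shared with the query — and keeps the top k
(default 20), turning an all-pairs comparison into a bounded blocking step.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .types import (
    NEGATIVE,
    POSITIVE,
    MappingRecord,
    OntologyClass,
    PathwayRecord,
    PredictionRecord,
)
from .corpus_io import build_string_representation

_WORD_RE = re.compile(r"[a-z0-9]+")

#: n-gram sizes used by the candidate selector and the bootstrap features.
DEFAULT_NGRAM_SIZES = frozenset({3, 4, 5})
DEFAULT_TOP_K = 20


def word_tokens(text: str) -> list[str]:
    """Lowercased word tokens: maximal alphanumeric runs, in order."""
    return _WORD_RE.findall(text.lower())


def char_ngrams(word: str, n: int) -> list[str]:
    """All contiguous within-word character n-grams (empty if word shorter)."""
    return [word[i : i + n] for i in range(len(word) - n + 1)]


def tokenize(text: str, ngram_sizes: Iterable[int] = DEFAULT_NGRAM_SIZES) -> frozenset[str]:
    """Token set of ``text``: word tokens plus namespaced character n-grams.

    N-gram tokens are prefixed ``"{n}#"`` so they can never collide with word
    tokens.  Empty text yields the empty set.
    """
    tokens: set[str] = set()
    sizes = tuple(ngram_sizes)
    for word in word_tokens(text):
        tokens.add(word)
        for n in sizes:
            for gram in char_ngrams(word, n):
                tokens.add(f"{n}#{gram}")
    return frozenset(tokens)


@dataclass
class IdfTable:
    """Corpus-wide token -> inverse-document-frequency weights.

    ``idf(t) = ln(doc_count / df(t)) + 1``.  A token never seen in the corpus
    is treated as maximally rare: lookup returns ``ln(doc_count) + 1``.
    """

    doc_count: int
    idf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.doc_count < 1:
            raise ValueError("doc_count must be >= 1")
        self._default = math.log(self.doc_count) + 1.0

    def __getitem__(self, token: str) -> float:
        return self.idf.get(token, self._default)

    def weight(self, tokens: Iterable[str]) -> float:
        # Summed in sorted token order so the result is bit-reproducible
        # regardless of how the token collection was built.
        return sum(self[t] for t in sorted(tokens))


def build_idf(
    corpus: Sequence[str], ngram_sizes: Iterable[int] = DEFAULT_NGRAM_SIZES
) -> IdfTable:
    """Build an :class:`IdfTable` over tokenised documents.

    Document frequency counts each document at most once per token.
    """
    if not corpus:
        raise ValueError("cannot build idf from an empty corpus")
    sizes = tuple(ngram_sizes)
    df: Counter[str] = Counter()
    for doc in corpus:
        df.update(tokenize(doc, sizes))
    n_docs = len(corpus)
    return IdfTable(
        doc_count=n_docs,
        idf={t: math.log(n_docs / count) + 1.0 for t, count in df.items()},
    )


def weighted_jaccard(a: frozenset[str], b: frozenset[str], idf: IdfTable) -> float:
    """Idf-weighted Jaccard index of two token sets; 0 for an empty union."""
    union = a | b
    if not union:
        return 0.0
    return idf.weight(a & b) / idf.weight(union)


def lexical_overlap_score(a: frozenset[str], b: frozenset[str], idf: IdfTable) -> float:
    """Sum of idf weights over the shared tokens (the blocking score)."""
    return idf.weight(a & b)


class CandidateSelector:
    """Top-k blocking over a fixed collection of target token sets.

    Built once from ``target_id -> token set``; :meth:`select` returns, for a
    query token set, the targets with any token overlap ranked by descending
    overlap score (ties by ascending target id), truncated to k.  An inverted
    index keeps per-query cost proportional to the query's token postings
    rather than the full target collection.
    """

    def __init__(self, target_tokens: Mapping[str, frozenset[str]], idf: IdfTable):
        self.target_tokens = dict(target_tokens)
        self.idf = idf
        self._index: dict[str, list[str]] = {}
        for target_id, tokens in self.target_tokens.items():
            for token in tokens:
                self._index.setdefault(token, []).append(target_id)

    def select(
        self, query: frozenset[str], k: int = DEFAULT_TOP_K
    ) -> list[tuple[str, float]]:
        if k < 1:
            raise ValueError("k must be >= 1")
        hits: set[str] = set()
        for token in query:
            hits.update(self._index.get(token, ()))
        # Scores are recomputed per hit (not accumulated along the postings)
        # so they are bit-identical to a direct overlap-score evaluation.
        scores = {
            target_id: lexical_overlap_score(query, self.target_tokens[target_id], self.idf)
            for target_id in hits
        }
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


def select_candidates(
    query: frozenset[str],
    targets: Mapping[str, frozenset[str]],
    idf: IdfTable,
    k: int = DEFAULT_TOP_K,
) -> list[tuple[str, float]]:
    """One-shot form of :class:`CandidateSelector` for a single query."""
    return CandidateSelector(targets, idf).select(query, k)


def entity_token_sets(
    entities: Mapping[str, OntologyClass] | Mapping[str, PathwayRecord],
    context: Mapping[str, OntologyClass] | Mapping[str, PathwayRecord] | None = None,
    ngram_sizes: Iterable[int] = DEFAULT_NGRAM_SIZES,
) -> dict[str, frozenset[str]]:
    """Token sets of the string representations of a collection of entities."""
    if context is None:
        context = entities
    sizes = tuple(ngram_sizes)
    return {
        entity_id: tokenize(build_string_representation(entity, context), sizes)
        for entity_id, entity in entities.items()
    }


def bow_predict(
    pathway: PathwayRecord,
    pathway_tokens: frozenset[str],
    class_tokens: Mapping[str, frozenset[str]],
    idf: IdfTable,
    threshold: float,
) -> list[PredictionRecord]:
    """Bag-of-words baseline: emit classes whose weighted Jaccard with the
    pathway's token set reaches ``threshold``, ranked by descending score.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    scored = [
        (class_id, weighted_jaccard(pathway_tokens, tokens, idf))
        for class_id, tokens in class_tokens.items()
    ]
    kept = sorted(
        ((cid, s) for cid, s in scored if s >= threshold and s > 0.0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return [
        PredictionRecord(pathway.pathway_id, cid, min(s, 1.0), rank)
        for rank, (cid, s) in enumerate(kept, start=1)
    ]


def fit_bow_threshold(scored_pairs: Sequence[tuple[float, str]]) -> float:
    """Grid-search the baseline's decision threshold on labelled pairs.

    ``scored_pairs`` holds ``(weighted_jaccard_score, label)`` tuples with
    labels ``positive`` / ``negative``.  Scans thresholds 0.01..0.99 in steps
    of 0.01 and returns the one maximising F1 of the positive class, ties
    broken by the smallest threshold.
    """
    labels = {label for _, label in scored_pairs}
    if POSITIVE not in labels or NEGATIVE not in labels:
        raise ValueError("threshold fitting needs both positive and negative pairs")
    n_pos = sum(1 for _, label in scored_pairs if label == POSITIVE)
    best_threshold, best_f1 = 0.01, -1.0
    for step in range(1, 100):
        threshold = step / 100.0
        tp = fp = 0
        for score, label in scored_pairs:
            if score >= threshold:
                if label == POSITIVE:
                    tp += 1
                else:
                    fp += 1
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_threshold = f1, threshold
    return best_threshold


def score_mapping_records(
    records: Iterable[MappingRecord],
    pathway_tokens: Mapping[str, frozenset[str]],
    class_tokens: Mapping[str, frozenset[str]],
    idf: IdfTable,
) -> list[tuple[float, str]]:
    """Weighted-Jaccard scores for labelled pairs, for threshold fitting."""
    return [
        (
            weighted_jaccard(
                pathway_tokens[rec.pathway_id], class_tokens[rec.class_id], idf
            ),
            rec.label,
        )
        for rec in records
        if rec.pathway_id in pathway_tokens and rec.class_id in class_tokens
    ]
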