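"""Score combination and ranked recommendation output.

For a candidate pair (pathway N, class M) every name pair in the Cartesian
product of the two entities' name lists is scored by the name matcher,
giving the set S_name = {s_ij}.  When both sides carry a definition the
definition matcher yields S_def and the combined score is

    S_total = w_name * max(S_name) + w_def * S_def        (w 0.75 / 0.25)

When either definition is missing the weights renormalise onto the name
term: S_total = max(S_name).  Candidates with S_total at or above the
output threshold (default 0.25) are emitted, ranked by descending score.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .lexical import DEFAULT_TOP_K, CandidateSelector
from .neural import DefinitionMatcher, NameMatcher
from .types import OntologyClass, PathwayRecord, PredictionRecord

DEFAULT_NAME_WEIGHT = 0.75
DEFAULT_DEF_WEIGHT = 0.25
DEFAULT_OUTPUT_THRESHOLD = 0.25


@dataclass
class CandidateScore:
    """Scores of one (pathway, class) candidate pair.

    ``total`` is recomputable from the stored components via
    :func:`combine_scores`.
    """

    pathway_id: str
    class_id: str
    name_scores: tuple[float, ...]
    def_score: float | None
    total: float


def combine_scores(
    name_scores: Sequence[float],
    def_score: float | None,
    w_name: float = DEFAULT_NAME_WEIGHT,
    w_def: float = DEFAULT_DEF_WEIGHT,
) -> float:
    """Weighted combination of the best name score and the definition score."""
    if not name_scores:
        raise ValueError("at least one name score is required")
    if abs(w_name + w_def - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    best_name = max(name_scores)
    if def_score is None:
        return best_name
    return w_name * best_name + w_def * def_score


def score_candidate_pair(
    pathway: PathwayRecord,
    cls: OntologyClass,
    name_matcher: NameMatcher,
    def_matcher: DefinitionMatcher | None,
    w_name: float = DEFAULT_NAME_WEIGHT,
    w_def: float = DEFAULT_DEF_WEIGHT,
) -> CandidateScore:
    """Score one candidate pair: all name pairs, plus definitions if present."""
    if not pathway.names or not cls.names:
        raise ValueError("both entities need at least one name")
    pairs = [(i, j) for i in pathway.names for j in cls.names]
    name_scores = tuple(
        float(s)
        for s in name_matcher.score_batch([a for a, _ in pairs], [b for _, b in pairs])
    )
    def_score: float | None = None
    if def_matcher is not None and pathway.definition and cls.definition:
        def_score = def_matcher.score(pathway.definition, cls.definition)
    total = combine_scores(name_scores, def_score, w_name, w_def)
    return CandidateScore(pathway.pathway_id, cls.class_id, name_scores, def_score, total)


def score_candidates(
    pathway: PathwayRecord,
    classes: Sequence[OntologyClass],
    name_matcher: NameMatcher,
    def_matcher: DefinitionMatcher | None,
    w_name: float = DEFAULT_NAME_WEIGHT,
    w_def: float = DEFAULT_DEF_WEIGHT,
) -> list[CandidateScore]:
    """Score one pathway against many classes, batching the matcher calls.

    Equivalent to mapping :func:`score_candidate_pair` over ``classes``; the
    name pairs of all candidates go through the name matcher in one batch
    and likewise the definition pairs, which matters when scoring thousands
    of candidate pairs.
    """
    if not classes:
        return []
    name_a: list[str] = []
    name_b: list[str] = []
    spans: list[tuple[int, int]] = []
    for cls in classes:
        if not pathway.names or not cls.names:
            raise ValueError("both entities need at least one name")
        start = len(name_a)
        for i in pathway.names:
            for j in cls.names:
                name_a.append(i)
                name_b.append(j)
        spans.append((start, len(name_a)))
    name_scores = name_matcher.score_batch(name_a, name_b)

    def_rows = [
        row
        for row, cls in enumerate(classes)
        if def_matcher is not None and pathway.definition and cls.definition
    ]
    def_scores: dict[int, float] = {}
    if def_rows:
        scores = def_matcher.score_batch(
            [pathway.definition] * len(def_rows),
            [classes[row].definition for row in def_rows],
        )
        def_scores = {row: float(s) for row, s in zip(def_rows, scores)}

    out: list[CandidateScore] = []
    for row, (cls, (start, end)) in enumerate(zip(classes, spans)):
        s_name = tuple(float(s) for s in name_scores[start:end])
        s_def = def_scores.get(row)
        out.append(
            CandidateScore(
                pathway.pathway_id,
                cls.class_id,
                s_name,
                s_def,
                combine_scores(s_name, s_def, w_name, w_def),
            )
        )
    return out


def predict_for_pathway(
    pathway: PathwayRecord,
    ontology: Mapping[str, OntologyClass],
    selector: CandidateSelector,
    pathway_tokens: frozenset[str],
    name_matcher: NameMatcher,
    def_matcher: DefinitionMatcher | None,
    threshold: float = DEFAULT_OUTPUT_THRESHOLD,
    k: int = DEFAULT_TOP_K,
    w_name: float = DEFAULT_NAME_WEIGHT,
    w_def: float = DEFAULT_DEF_WEIGHT,
) -> list[PredictionRecord]:
    """Recommendations for one pathway over its top-k lexical candidates."""
    candidates = selector.select(pathway_tokens, k=k)
    scored = score_candidates(
        pathway,
        [ontology[class_id] for class_id, _overlap in candidates],
        name_matcher,
        def_matcher,
        w_name,
        w_def,
    )
    kept = sorted(
        (c for c in scored if c.total >= threshold),
        key=lambda c: (-c.total, c.class_id),
    )
    return [
        PredictionRecord(pathway.pathway_id, c.class_id, min(max(c.total, 0.0), 1.0), rank)
        for rank, c in enumerate(kept, start=1)
    ]


def predict_all(
    database: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
    selector: CandidateSelector,
    pathway_tokens: Mapping[str, frozenset[str]],
    name_matcher: NameMatcher,
    def_matcher: DefinitionMatcher | None,
    threshold: float = DEFAULT_OUTPUT_THRESHOLD,
    k: int = DEFAULT_TOP_K,
    w_name: float = DEFAULT_NAME_WEIGHT,
    w_def: float = DEFAULT_DEF_WEIGHT,
) -> list[PredictionRecord]:
    """Recommendations for every pathway, grouped in input order.

    Pathways with no surviving candidates contribute an empty group; they
    still count in the yield denominator downstream.
    """
    out: list[PredictionRecord] = []
    for pathway_id, pathway in database.items():
        out.extend(
            predict_for_pathway(
                pathway,
                ontology,
                selector,
                pathway_tokens[pathway_id],
                name_matcher,
                def_matcher,
                threshold,
                k,
                w_name,
                w_def,
            )
        )
    return out
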