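"""Assembly of the labelled training table.

Positives come from existing curated pathway-to-class mappings (and,
optionally, distant-supervision pairs such as GO-to-MeSH term mappings).
Negatives are sampled per ontology class: *easy* negatives uniformly at
random from the pathway database, *hard* negatives from the lexically
most-similar pathways via a reverse candidate selector, always excluding
the class's known positives.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .lexical import CandidateSelector
from .types import (
    NEGATIVE,
    POSITIVE,
    MappingRecord,
    OntologyClass,
    PathwayRecord,
    TrainingPair,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Labelled text-bundle pairs plus per-(label, source) bookkeeping.

    Invariant: no (a_id, b_id) pair carries both labels — when a pair arrives
    with both, the positive wins and the negative is dropped.
    """

    pairs: list[TrainingPair] = field(default_factory=list)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        return dict(Counter((p.label, p.source) for p in self.pairs))

    @property
    def positives(self) -> list[TrainingPair]:
        return [p for p in self.pairs if p.label == POSITIVE]

    @property
    def negatives(self) -> list[TrainingPair]:
        return [p for p in self.pairs if p.label == NEGATIVE]

    def pair_ids(self) -> set[tuple[str, str]]:
        return {p.pair for p in self.pairs}

    def extend(self, new_pairs: Iterable[TrainingPair]) -> None:
        existing = self.pair_ids()
        positive_ids = {p.pair for p in self.pairs if p.label == POSITIVE}
        for pair in new_pairs:
            if pair.pair in existing:
                continue
            if pair.label == NEGATIVE and pair.pair in positive_ids:
                continue
            self.pairs.append(pair)
            existing.add(pair.pair)
            if pair.label == POSITIVE:
                positive_ids.add(pair.pair)


def extract_positives(
    mapping_tables: Sequence[Iterable[MappingRecord]],
    database: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
) -> tuple[list[MappingRecord], int]:
    """Deduplicated positive records from one or more mapping tables.

    Rows whose pathway or class id does not resolve are dropped; the second
    return value is the dropped-row count.
    """
    seen: set[tuple[str, str]] = set()
    positives: list[MappingRecord] = []
    dropped = 0
    for table in mapping_tables:
        for rec in table:
            if rec.label != POSITIVE:
                continue
            if rec.pathway_id not in database or rec.class_id not in ontology:
                dropped += 1
                continue
            if rec.pair in seen:
                continue
            seen.add(rec.pair)
            positives.append(rec)
    if dropped:
        logger.warning("dropped %d unresolvable positive mapping rows", dropped)
    return positives, dropped


def sample_easy_negatives(
    cls: OntologyClass,
    database: Mapping[str, PathwayRecord],
    positives: Iterable[MappingRecord],
    n: int = 2,
    seed: int = 0,
) -> list[MappingRecord]:
    """Uniform-random non-matching pathways for one class, seeded.

    Returns fewer than ``n`` records when the database holds fewer
    non-positive pathways.
    """
    positive_pathways = {
        rec.pathway_id for rec in positives if rec.class_id == cls.class_id
    }
    pool = sorted(pid for pid in database if pid not in positive_pathways)
    if not pool or n <= 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [
        MappingRecord(pool[i], cls.class_id, NEGATIVE, source="easy_negative")
        for i in sorted(chosen)
    ]


def sample_hard_negatives(
    cls: OntologyClass,
    class_tokens: frozenset[str],
    reverse_selector: CandidateSelector,
    positives: Iterable[MappingRecord],
    n: int = 2,
) -> list[MappingRecord]:
    """Highest lexical-overlap pathways for one class that are not positives.

    ``reverse_selector`` indexes *pathway* string representations and is
    queried with the class's token set — the mirror image of the
    pathway-to-class selector used at prediction time.
    """
    if n <= 0:
        return []
    positive_pathways = {
        rec.pathway_id for rec in positives if rec.class_id == cls.class_id
    }
    # Over-fetch so that filtering out positives still leaves n candidates.
    ranked = reverse_selector.select(class_tokens, k=n + len(positive_pathways) + 5)
    out: list[MappingRecord] = []
    for pathway_id, _score in ranked:
        if pathway_id in positive_pathways:
            continue
        out.append(MappingRecord(pathway_id, cls.class_id, NEGATIVE, source="hard_negative"))
        if len(out) == n:
            break
    return out


def _pair_from_mapping(
    rec: MappingRecord,
    database: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
) -> TrainingPair:
    pathway = database[rec.pathway_id]
    cls = ontology[rec.class_id]
    return TrainingPair(
        a_id=rec.pathway_id,
        b_id=rec.class_id,
        a_name=pathway.names[0],
        b_name=cls.name,
        label=rec.label,
        source=rec.source,
        a_aliases=tuple(pathway.names[1:]),
        b_aliases=tuple(cls.aliases),
        a_def=pathway.definition,
        b_def=cls.definition,
    )


def assemble_training_set(
    positives: Iterable[MappingRecord],
    negatives: Iterable[MappingRecord],
    database: Mapping[str, PathwayRecord],
    ontology: Mapping[str, OntologyClass],
    go_mesh_pairs: Iterable[TrainingPair] = (),
) -> TrainingSet:
    """Merge positives, sampled negatives and distant-supervision pairs.

    Positives take precedence: a pair present with both labels keeps only its
    positive record.  GO/MeSH-style pairs are appended as-is (they are text
    bundles, not resolved against the ontology) under their own source tag.
    """
    training = TrainingSet()
    training.extend(_pair_from_mapping(rec, database, ontology) for rec in positives)
    training.extend(_pair_from_mapping(rec, database, ontology) for rec in negatives)
    training.extend(go_mesh_pairs)
    for label, source in sorted(training.counts):
        logger.info("training pairs %s/%s: %d", label, source, training.counts[(label, source)])
    return training


def sample_all_negatives(
    ontology: Mapping[str, OntologyClass],
    database: Mapping[str, PathwayRecord],
    class_tokens: Mapping[str, frozenset[str]],
    reverse_selector: CandidateSelector,
    positives: Sequence[MappingRecord],
    n_easy: int = 2,
    n_hard: int = 2,
    seed: int = 0,
) -> list[MappingRecord]:
    """Easy + hard negatives for every ontology class, deduplicated.

    Per-class seeds are derived from ``seed`` so the whole sample is
    reproducible yet classes draw independently.
    """
    rng = np.random.default_rng(seed)
    negatives: dict[tuple[str, str], MappingRecord] = {}
    for class_id in sorted(ontology):
        cls = ontology[class_id]
        class_seed = int(rng.integers(0, 2**31 - 1))
        for rec in sample_easy_negatives(cls, database, positives, n_easy, class_seed):
            negatives.setdefault(rec.pair, rec)
        for rec in sample_hard_negatives(
            cls, class_tokens[class_id], reverse_selector, positives, n_hard
        ):
            negatives.setdefault(rec.pair, rec)
    return list(negatives.values())
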