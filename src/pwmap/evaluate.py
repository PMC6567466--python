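"""Curator-facing evaluation metrics and inter-rater agreement.

Recommendations are graded by curators as *yes* (exact match), *related*
(maps to a parent, child or sibling class) or *no*.  Three metrics summarise
a model's usefulness to a curation pipeline:

* **precision per mapping (ppm)** — fraction of graded pairs rated yes or
  related: how correct each recommendation is;
* **recall per pathway (rpp)** — fraction of pathways with at least one
  yes-or-related recommendation: how often the curator finds something
  usable in the list;
* **yield** — fraction of pathways receiving any recommendation at all.

Agreement between two raters over the three nominal categories is measured
by raw percent agreement and unweighted Cohen's kappa on the 3x3
contingency table.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .types import CURATION_LABELS, RELATED, YES, CurationLabel, PredictionRecord


def precision_per_mapping(labels: Sequence[CurationLabel]) -> float:
    """(#yes + #related) / #graded pairs."""
    if not labels:
        raise ValueError("cannot compute precision over zero graded pairs")
    good = sum(1 for lab in labels if lab.label in (YES, RELATED))
    return good / len(labels)


def recall_per_pathway(
    labels: Iterable[CurationLabel], pathway_universe: Iterable[str]
) -> float:
    """Fraction of universe pathways with >= 1 yes-or-related grade.

    Pathways that received no recommendations appear only in the denominator.
    """
    universe = set(pathway_universe)
    if not universe:
        raise ValueError("pathway universe must be non-empty")
    hit: set[str] = set()
    for lab in labels:
        if lab.pathway_id not in universe:
            raise ValueError(f"labelled pathway {lab.pathway_id!r} outside the universe")
        if lab.label in (YES, RELATED):
            hit.add(lab.pathway_id)
    return len(hit) / len(universe)


def prediction_yield(
    predictions: Iterable[PredictionRecord], pathway_universe: Iterable[str]
) -> float:
    """Fraction of universe pathways receiving any recommendation."""
    universe = set(pathway_universe)
    if not universe:
        raise ValueError("pathway universe must be non-empty")
    covered = {p.pathway_id for p in predictions} & universe
    return len(covered) / len(universe)


@dataclass
class ContingencyTable3:
    """3x3 rater-by-rater counts over the yes/related/no categories.

    Rows index rater 1's label, columns rater 2's, both in the order
    (yes, related, no).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("contingency table must hold at least one pair")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_contingency(
    labels_r1: Sequence[CurationLabel], labels_r2: Sequence[CurationLabel]
) -> ContingencyTable3:
    """Cross-tabulate two raters' grades over the identical pair set."""
    by_pair_1 = {(l.pathway_id, l.class_id): l.label for l in labels_r1}
    by_pair_2 = {(l.pathway_id, l.class_id): l.label for l in labels_r2}
    if set(by_pair_1) != set(by_pair_2):
        diff = sorted(set(by_pair_1) ^ set(by_pair_2))
        raise ValueError(f"raters graded different pair sets; symmetric difference: {diff}")
    index = {label: i for i, label in enumerate(CURATION_LABELS)}
    counts = np.zeros((3, 3))
    for pair, label1 in by_pair_1.items():
        counts[index[label1], index[by_pair_2[pair]]] += 1
    return ContingencyTable3(counts)


def percent_agreement(table: ContingencyTable3) -> float:
    """Observed agreement: trace / total."""
    return float(np.trace(table.counts)) / table.total


def cohens_kappa(table: ContingencyTable3) -> float:
    """Unweighted Cohen's kappa for the three nominal categories.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginal products.
    """
    total = table.total
    p_o = float(np.trace(table.counts)) / total
    rows = table.counts.sum(axis=1)
    cols = table.counts.sum(axis=0)
    p_e = float(rows @ cols) / total**2
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def round_half_up(value: float, digits: int = 2) -> float:
    """Half-up rounding used when reporting metrics."""
    factor = 10**digits
    return np.floor(value * factor + 0.5) / factor


def evaluate_predictions(
    predictions: Sequence[PredictionRecord],
    labels: Mapping[tuple[str, str], str],
    pathway_universe: Iterable[str],
) -> dict[str, float]:
    """ppm, rpp and yield of a prediction list against graded labels."""
    graded = [
        CurationLabel(p.pathway_id, p.class_id, labels[(p.pathway_id, p.class_id)])
        for p in predictions
        if (p.pathway_id, p.class_id) in labels
    ]
    universe = list(pathway_universe)
    return {
        "ppm": precision_per_mapping(graded) if graded else 0.0,
        "rpp": recall_per_pathway(graded, universe),
        "yield": prediction_yield(predictions, universe),
    }
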