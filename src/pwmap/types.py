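"""Core domain types shared across the mapping pipeline.

The package links *pathway records* (entries of a source pathway database
such as Reactome, KEGG or SMPDB) to *ontology classes* (terms of a pathway
ontology with subclass and part-of hierarchies).  Everything downstream —
lexical blocking, training-pair assembly, neural scoring, evaluation —
operates on the small set of dataclasses defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OntologyClass:
    """One ontology class: identifier, names, definition and hierarchy links.

    ``subclass_parents`` and ``part_of_parents`` hold direct parents in the
    two hierarchies; ``children`` is the inverse of ``subclass_parents`` and
    is filled in by the ontology reader, not by hand.
    """

    class_id: str
    name: str
    aliases: list[str] = field(default_factory=list)
    definition: str | None = None
    subclass_parents: list[str] = field(default_factory=list)
    part_of_parents: list[str] = field(default_factory=list)
    children: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        """Canonical name first, then aliases."""
        return [self.name, *self.aliases]


@dataclass
class PathwayRecord:
    """One pathway entry of a source database.

    ``names`` holds the canonical name first, then aliases.  ``definition``
    is ``None`` when the database provides no free-text description —
    an absent definition is semantically different from an empty string
    and the score combiner treats it specially.
    """

    pathway_id: str
    source_db: str
    names: list[str]
    definition: str | None = None
    parent_ids: list[str] = field(default_factory=list)
    child_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names or not self.names[0]:
            raise ValueError(f"pathway {self.pathway_id!r} has no name")


POSITIVE = "positive"
NEGATIVE = "negative"
VALID_LABELS = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class MappingRecord:
    """A labelled (pathway, class) pair with provenance.

    ``source`` records where the label came from, e.g. ``pw_existing`` for
    curated mappings shipped with the ontology, ``easy_negative`` /
    ``hard_negative`` for sampled negatives, ``go_mesh`` for distant
    supervision, ``bootstrap`` for self-training output.
    """

    pathway_id: str
    class_id: str
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"invalid label {self.label!r} for pair "
                f"({self.pathway_id}, {self.class_id}); expected one of {VALID_LABELS}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.pathway_id, self.class_id)


@dataclass(frozen=True)
class PredictionRecord:
    """A recommended (pathway, class) mapping with a combined score and rank.

    Ranks start at 1 within each pathway group and scores are non-increasing
    with rank.
    """

    pathway_id: str
    class_id: str
    score: float
    rank: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.rank < 1:
            raise ValueError(f"rank {self.rank} must be >= 1")


@dataclass(frozen=True)
class TrainingPair:
    """One text-bundle pair for the matchers: two sides, a label, provenance.

    ``a_name`` / ``b_name`` are the canonical names, ``a_aliases`` /
    ``b_aliases`` any synonyms, and ``a_def`` / ``b_def`` the optional
    definitions.  Side *a* is the pathway side, side *b* the class side;
    distant-supervision pairs (e.g. GO/MeSH) use the same shape without
    resolving against a loaded ontology.
    """

    a_id: str
    b_id: str
    a_name: str
    b_name: str
    label: str
    source: str = ""
    a_aliases: tuple[str, ...] = ()
    b_aliases: tuple[str, ...] = ()
    a_def: str | None = None
    b_def: str | None = None

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a_id, self.b_id)

    @property
    def a_names(self) -> list[str]:
        return [self.a_name, *self.a_aliases]

    @property
    def b_names(self) -> list[str]:
        return [self.b_name, *self.b_aliases]


YES = "yes"
RELATED = "related"
NO = "no"
CURATION_LABELS = (YES, RELATED, NO)


@dataclass(frozen=True)
class CurationLabel:
    """A curator's grade for one recommended (pathway, class) pair."""

    pathway_id: str
    class_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in CURATION_LABELS:
            raise ValueError(
                f"invalid curation label {self.label!r}; expected one of {CURATION_LABELS}"
            )
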