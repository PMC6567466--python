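"""Synthetic fixture generator: an ontology, noisy pathway databases with
known ground-truth mappings, synonym-aware token embeddings and simulated
curator grades.

The generator emulates the real curation setting — an ontology of pathway
classes with names, synonyms and definitions, and several pathway databases
whose entries describe the same processes in slightly different words — at
a scale where every pipeline stage can be exercised and checked against the
known truth.  Pathway records are derived from ontology classes by lexical
perturbation: per-token synonym substitution, token dropout, typo injection
and definition paraphrase, each at a configurable rate.  Because each
pathway remembers its source class, curator grades (yes / related / no) can
be simulated exactly from the class hierarchy.

All generators take explicit seeds; there is no hidden global randomness.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .neural import EmbeddingStore
from .types import (
    NO,
    RELATED,
    YES,
    CurationLabel,
    OntologyClass,
    PathwayRecord,
    PredictionRecord,
)

# Stems and suffixes combine into a few hundred biological-sounding word
# tokens; no external corpus is needed.
_STEMS = [
    "glyc", "lip", "prote", "apopt", "oxid", "phosph", "nucle", "mit",
    "chrom", "ribos", "lys", "cytos", "kin", "hydrol", "transl", "transcript",
    "metabol", "cataly", "synth", "degrad", "signal", "recept", "membran",
    "vesic", "endocyt", "exocyt", "autophag", "prolifer", "differenti",
    "migrat", "adhes", "inflamm", "immun", "hormon", "steroid", "peptid",
    "glucos", "fruct", "lact", "pyruv", "citr", "malat", "fumar", "succin",
    "acet", "butyr", "palmit", "ole", "arachidon", "prostagland",
]
_SUFFIXES = ["olysis", "ogenesis", "ation", "osis", "emia", "ase", "ine", "ide"]

_TEMPLATE_WORDS = [
    "pathway", "process", "cell", "activity", "regulated", "through",
    "involving", "mediated", "response", "cascade", "the", "a", "in", "is",
    "of", "by", "this", "describes", "how", "via",
]

# Synonyms for template words used by the definition paraphraser.
_TEMPLATE_SYNONYMS = {
    "pathway": ["cascade"],
    "regulated": ["mediated"],
    "through": ["via"],
    "cell": ["cellular"],
}


def build_vocabulary(seed: int = 0, max_groups: int | None = None) -> list[list[str]]:
    """Synonym groups of synthetic biomedical tokens.

    Each group holds one base token plus 0-2 morphological variants that the
    generator treats as synonymous (and that the synthetic embeddings place
    close together).
    """
    rng = np.random.default_rng(seed)
    groups: list[list[str]] = []
    for stem, suffix in itertools.product(_STEMS, _SUFFIXES):
        base = stem + suffix
        group = [base]
        n_syn = int(rng.integers(0, 3))
        variants = [base + "ic", "trans" + base, base + "al"]
        group.extend(variants[:n_syn])
        groups.append(group)
    for word in _TEMPLATE_WORDS:
        groups.append([word, *_TEMPLATE_SYNONYMS.get(word, [])])
    if max_groups is not None:
        groups = groups[:max_groups]
    return groups


@dataclass
class NoiseConfig:
    """Per-token perturbation rates applied when deriving pathway records."""

    synonym_rate: float = 0.0
    dropout_rate: float = 0.0
    typo_rate: float = 0.0
    paraphrase_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("synonym_rate", "dropout_rate", "typo_rate", "paraphrase_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            min(self.synonym_rate * factor, 1.0),
            min(self.dropout_rate * factor, 1.0),
            min(self.typo_rate * factor, 1.0),
            min(self.paraphrase_rate * factor, 1.0),
        )


#: Moderate noise: enough lexical drift that exact string matching starts to
#: miss, while names remain recognisably derived from their class.
MODERATE_NOISE = NoiseConfig(
    synonym_rate=0.3, dropout_rate=0.15, typo_rate=0.1, paraphrase_rate=0.3
)


@dataclass
class SyntheticCorpus:
    """Everything one run of the pipeline needs, with ground truth attached."""

    ontology: dict[str, OntologyClass]
    databases: dict[str, dict[str, PathwayRecord]]
    truth: dict[str, list[tuple[str, str]]]  # db name -> (pathway_id, class_id)
    embeddings: EmbeddingStore
    noise_config: NoiseConfig
    synonym_groups: list[list[str]] = field(default_factory=list)

    def truth_map(self, db_name: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pathway_id, class_id in self.truth[db_name]:
            out.setdefault(pathway_id, set()).add(class_id)
        return out


def make_ontology(
    n_classes: int,
    depth: int = 6,
    branching: int = 3,
    vocab: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, OntologyClass]:
    """Tree-shaped subclass hierarchy of multi-word pathway classes.

    The root is named ``pathway``; each child extends its parent's name with
    one fresh specialiser token, so every non-root name shares tokens with
    its parent's.  Classes get 0-2 synonym-substituted aliases and a
    templated definition.  Deterministic under ``seed``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    groups = [list(g) for g in (vocab if vocab is not None else build_vocabulary(seed))]
    specializer_groups = [g for g in groups if g[0] not in _TEMPLATE_WORDS]
    if len(specializer_groups) < n_classes:
        raise ValueError(
            f"vocabulary exhausted: {len(specializer_groups)} groups for {n_classes} classes"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(specializer_groups))
    group_iter = iter(order)
    by_token = {g[0]: g for g in groups}

    def class_id(i: int) -> str:
        return f"SPW:{i:07d}"

    ontology: dict[str, OntologyClass] = {}
    root = OntologyClass(class_id(0), "pathway", definition=_make_definition([], "pathway", rng))
    ontology[root.class_id] = root
    # (id, specializer tokens, depth)
    queue: list[tuple[str, list[str], int]] = [(root.class_id, [], 0)]
    next_index = 1
    while next_index < n_classes:
        if not queue:
            raise ValueError("hierarchy exhausted before n_classes reached; increase depth/branching")
        parent_id, parent_specs, parent_depth = queue.pop(0)
        if parent_depth >= depth:
            continue
        for _ in range(branching):
            if next_index >= n_classes:
                break
            try:
                group = specializer_groups[next(group_iter)]
            except StopIteration:
                raise ValueError("vocabulary exhausted while naming classes") from None
            specs = [*parent_specs, group[0]]
            name = " ".join([*specs, "pathway"])
            aliases = _make_aliases(specs, by_token, rng)
            cls = OntologyClass(
                class_id(next_index),
                name,
                aliases=aliases,
                definition=_make_definition(specs, "pathway", rng),
                subclass_parents=[parent_id],
            )
            ontology[cls.class_id] = cls
            ontology[parent_id].children.append(cls.class_id)
            queue.append((cls.class_id, specs, parent_depth + 1))
            next_index += 1
    return ontology


def _make_definition(specs: list[str], head: str, rng: np.random.Generator) -> str:
    subject = " ".join(specs) if specs else "biological"
    filler = _STEMS[int(rng.integers(0, len(_STEMS)))] + "ation"
    return (
        f"a {head} in which {subject} activity is regulated through "
        f"{filler} mediated response in the cell"
    )


def _make_aliases(
    specs: list[str], by_token: Mapping[str, list[str]], rng: np.random.Generator
) -> list[str]:
    aliases: list[str] = []
    for _ in range(int(rng.integers(0, 3))):
        tokens = [*specs, "pathway"]
        swappable = [i for i, t in enumerate(tokens) if len(by_token.get(t, [t])) > 1]
        if not swappable:
            break
        i = int(rng.choice(swappable))
        group = by_token[tokens[i]]
        tokens[i] = group[1 + int(rng.integers(0, len(group) - 1))]
        alias = " ".join(tokens)
        if alias not in aliases:
            aliases.append(alias)
    return aliases


def _apply_typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 1))
    return word[:i] + word[i + 1] + word[i] + word[i + 2 :]  # adjacent swap


def _perturb_tokens(
    tokens: list[str],
    noise: NoiseConfig,
    by_token: Mapping[str, list[str]],
    rng: np.random.Generator,
    keep_index: int | None,
) -> list[str]:
    """Synonym-substitute / drop / typo tokens; the token at ``keep_index``
    is never dropped, so a name always retains at least one token."""
    out: list[str] = []
    for i, token in enumerate(tokens):
        if i != keep_index and rng.random() < noise.dropout_rate:
            continue
        word = token
        group = by_token.get(word, [word])
        if len(group) > 1 and rng.random() < noise.synonym_rate:
            word = group[1 + int(rng.integers(0, len(group) - 1))]
        if rng.random() < noise.typo_rate:
            word = _apply_typo(word, rng)
        out.append(word)
    return out


def make_pathway_db(
    ontology: Mapping[str, OntologyClass],
    db_name: str,
    pathways_per_class: int = 1,
    noise: NoiseConfig = NoiseConfig(),
    definition_presence_rate: float = 1.0,
    vocab: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, PathwayRecord], list[tuple[str, str]]]:
    """Derive a noisy pathway database from the ontology, with ground truth.

    Each pathway perturbs one class's name token-by-token; with zero noise
    the names are identical.  The most specific name token (the last
    specialiser, or the head for the root) is never dropped.  Definitions
    are paraphrased class definitions, present at the given rate.  Pathway
    parent/child links mirror the class hierarchy within the same replicate.
    """
    if not 0.0 <= definition_presence_rate <= 1.0:
        raise ValueError("definition_presence_rate outside [0, 1]")
    groups = [list(g) for g in (vocab if vocab is not None else build_vocabulary(seed))]
    by_token = {t: g for g in groups for t in g}
    rng = np.random.default_rng(seed)

    class_ids = sorted(ontology)
    pathway_id_of: dict[tuple[str, int], str] = {
        (cid, rep): f"{db_name}:{i * pathways_per_class + rep:06d}"
        for i, cid in enumerate(class_ids)
        for rep in range(pathways_per_class)
    }
    records: dict[str, PathwayRecord] = {}
    truth: list[tuple[str, str]] = []
    for cid in class_ids:
        cls = ontology[cid]
        name_tokens = cls.name.split()
        keep = max(len(name_tokens) - 2, 0)  # last specialiser (head for root)
        for rep in range(pathways_per_class):
            pid = pathway_id_of[(cid, rep)]
            tokens = _perturb_tokens(name_tokens, noise, by_token, rng, keep)
            names = [" ".join(tokens)]
            if cls.aliases and rng.random() < 0.3:
                alias_tokens = _perturb_tokens(
                    cls.aliases[0].split(), noise, by_token, rng, keep
                )
                alias = " ".join(alias_tokens)
                if alias and alias not in names:
                    names.append(alias)
            definition = None
            if cls.definition and rng.random() < definition_presence_rate:
                def_tokens = _perturb_tokens(
                    cls.definition.split(),
                    NoiseConfig(synonym_rate=noise.paraphrase_rate),
                    by_token,
                    rng,
                    keep_index=None,
                )
                definition = " ".join(def_tokens)
            parent_ids = [
                pathway_id_of[(p, rep)]
                for p in cls.subclass_parents
                if (p, rep) in pathway_id_of
            ]
            child_ids = [
                pathway_id_of[(ch, rep)]
                for ch in cls.children
                if (ch, rep) in pathway_id_of
            ]
            records[pid] = PathwayRecord(
                pathway_id=pid,
                source_db=db_name,
                names=names,
                definition=definition,
                parent_ids=parent_ids,
                child_ids=child_ids,
            )
            truth.append((pid, cid))
    return records, truth


def make_embeddings(
    synonym_groups: Iterable[Sequence[str]], dim: int = 200, seed: int = 0
) -> EmbeddingStore:
    """Seeded token embeddings in which synonymous tokens sit close together.

    Each synonym group draws a unit-scale centroid; members are the centroid
    plus small jitter, so within-group cosine similarity is high (> 0.9)
    while unrelated tokens are near-orthogonal at high dimension.  ``dim``
    must be even, mirroring the two concatenated 100-d halves of the real
    pre-trained vectors.
    """
    if dim % 2 != 0:
        raise ValueError("embedding dim must be even (two concatenated halves)")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dim)
    vectors: dict[str, np.ndarray] = {}
    for group in synonym_groups:
        centroid = rng.normal(0.0, scale, size=dim)
        for token in group:
            if token in vectors:
                continue
            vectors[token] = centroid + rng.normal(0.0, 0.12 * scale, size=dim)
    return EmbeddingStore(dim=dim, vectors=vectors)


def _related_classes(class_id: str, ontology: Mapping[str, OntologyClass]) -> set[str]:
    """Parents, children and siblings (classes sharing a subclass parent)."""
    cls = ontology[class_id]
    related: set[str] = set()
    parents = [*cls.subclass_parents, *cls.part_of_parents]
    related.update(parents)
    related.update(cls.children)
    for parent_id in cls.subclass_parents:
        parent = ontology.get(parent_id)
        if parent is not None:
            related.update(parent.children)
    related.discard(class_id)
    return related


def make_curation_labels(
    predictions: Iterable[PredictionRecord],
    truth: Mapping[str, set[str]],
    ontology: Mapping[str, OntologyClass],
) -> list[CurationLabel]:
    """Simulated curator grades from the ground truth and class hierarchy.

    *yes* if the predicted class is a truth class of the pathway, *related*
    if it is a parent, child or sibling of one, else *no* — the same rule
    human curators apply, made exact by the known truth.
    """
    labels: list[CurationLabel] = []
    for pred in predictions:
        truth_classes = truth.get(pred.pathway_id, set())
        if pred.class_id in truth_classes:
            grade = YES
        else:
            related = set()
            for tc in truth_classes:
                if tc in ontology:
                    related |= _related_classes(tc, ontology)
            grade = RELATED if pred.class_id in related else NO
        labels.append(CurationLabel(pred.pathway_id, pred.class_id, grade))
    return labels


def make_corpus(
    n_classes: int = 150,
    pathways_per_class: int = 2,
    depth: int = 6,
    branching: int = 3,
    noise: NoiseConfig = MODERATE_NOISE,
    definition_presence_rate: float = 0.8,
    dim: int = 200,
    seed: int = 0,
) -> SyntheticCorpus:
    """Default synthetic study corpus.

    Two databases derive from one ontology: ``source`` (one pathway per
    class, at reduced noise) plays the role of the already-mapped databases
    whose curated mappings seed training; ``target`` (``pathways_per_class``
    pathways per class, full noise) plays the role of the database being
    mapped, its truth held out for evaluation.
    """
    vocab = build_vocabulary(seed)
    ontology = make_ontology(n_classes, depth, branching, vocab, seed=seed)
    source, source_truth = make_pathway_db(
        ontology,
        "SRC",
        pathways_per_class=1,
        noise=noise.scaled(0.5),
        definition_presence_rate=definition_presence_rate,
        vocab=vocab,
        seed=seed + 1,
    )
    target, target_truth = make_pathway_db(
        ontology,
        "TGT",
        pathways_per_class=pathways_per_class,
        noise=noise,
        definition_presence_rate=definition_presence_rate,
        vocab=vocab,
        seed=seed + 2,
    )
    embeddings = make_embeddings(vocab, dim=dim, seed=seed + 3)
    return SyntheticCorpus(
        ontology=ontology,
        databases={"source": source, "target": target},
        truth={"source": source_truth, "target": target_truth},
        embeddings=embeddings,
        noise_config=noise,
        synonym_groups=vocab,
    )
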