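"""Readers and writers for ontologies, pathway records, mapping tables and
predictions, plus the per-entity string representation used by all lexical
operations.

File conventions
----------------
* Ontology: OBO 1.2/1.4, read through :mod:`obonet`.  Obsolete terms are
  skipped; ``alt_id`` lines are ignored.
* Pathways / mappings / predictions: UTF-8 TSV with a header row; list-valued
  cells (aliases, parents, children) are pipe-``|`` delimited.  Pathways may
  alternatively be read from JSON-lines with the same keys.
"""

from __future__ import annotations

import csv
import json
import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import obonet

from .types import (
    MappingRecord,
    OntologyClass,
    PathwayRecord,
    PredictionRecord,
)

logger = logging.getLogger(__name__)

_PATHWAY_COLUMNS = ["id", "source", "name", "aliases", "definition", "parents", "children"]


def _unquote(value: str) -> str:
    """Extract the quoted text of an OBO ``def:`` or ``synonym:`` value."""
    value = value.strip()
    if value.startswith('"'):
        end = value.find('"', 1)
        if end > 0:
            return value[1:end]
    return value


def _check_duplicate_term_ids(path: str | Path) -> None:
    # obonet silently merges duplicate stanzas; detect them with a line scan.
    seen: set[str] = set()
    in_term = False
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
            elif in_term and line.startswith("id:"):
                term_id = line[3:].strip()
                if term_id in seen:
                    raise ValueError(f"duplicate term id {term_id!r} at line {lineno}")
                seen.add(term_id)
                in_term = False  # only the first id: line of a stanza counts


def read_ontology_obo(path: str | Path) -> dict[str, OntologyClass]:
    """Read an OBO ontology into a ``class_id -> OntologyClass`` map.

    Synonym lines populate ``aliases``; ``is_a`` and ``relationship: part_of``
    populate the two parent lists; ``children`` is computed as the inverse of
    ``subclass_parents``.  Obsolete terms are skipped.

    Raises
    ------
    ValueError
        On a duplicate term id (with the offending line number) or a stanza
        obonet cannot parse.
    """
    _check_duplicate_term_ids(path)
    graph = obonet.read_obo(str(path), ignore_obsolete=True)

    ontology: dict[str, OntologyClass] = {}
    for class_id, data in graph.nodes(data=True):
        aliases = [_unquote(s) for s in data.get("synonym", [])]
        definition = _unquote(data["def"]) if "def" in data else None
        part_of = []
        for rel in data.get("relationship", []):
            parts = rel.split()
            if len(parts) == 2 and parts[0] == "part_of":
                part_of.append(parts[1])
        ontology[class_id] = OntologyClass(
            class_id=class_id,
            name=data.get("name", class_id),
            aliases=aliases,
            definition=definition,
            subclass_parents=list(data.get("is_a", [])),
            part_of_parents=part_of,
        )

    for cls in ontology.values():
        for parent_id in cls.subclass_parents:
            parent = ontology.get(parent_id)
            if parent is not None and cls.class_id not in parent.children:
                parent.children.append(cls.class_id)
    return ontology


def write_ontology_obo(ontology: Mapping[str, OntologyClass], path: str | Path) -> None:
    """Write an ontology as OBO (inverse of :func:`read_ontology_obo`)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        for class_id in sorted(ontology):
            cls = ontology[class_id]
            handle.write(f"\n[Term]\nid: {cls.class_id}\nname: {cls.name}\n")
            if cls.definition:
                handle.write(f'def: "{cls.definition}" []\n')
            for alias in cls.aliases:
                handle.write(f'synonym: "{alias}" EXACT []\n')
            for parent in cls.subclass_parents:
                handle.write(f"is_a: {parent}\n")
            for parent in cls.part_of_parents:
                handle.write(f"relationship: part_of {parent}\n")


def _split_cell(cell: str) -> list[str]:
    return [part for part in cell.split("|") if part] if cell else []


def _pathway_from_fields(
    row_id: str,
    source: str,
    name: str,
    aliases: list[str],
    definition: str | None,
    parents: list[str],
    children: list[str],
    where: str,
) -> PathwayRecord:
    if not row_id:
        raise ValueError(f"missing pathway id at {where}")
    if not name:
        raise ValueError(f"missing pathway name at {where}")
    return PathwayRecord(
        pathway_id=row_id,
        source_db=source,
        names=[name, *aliases],
        definition=definition or None,
        parent_ids=parents,
        child_ids=children,
    )


def read_pathway_records(
    path: str | Path, format: str = "tsv"
) -> dict[str, PathwayRecord]:
    """Read pathway records from TSV or JSON-lines into an id-keyed map.

    An empty definition cell yields ``definition is None``, never an empty
    string.  A row missing its id or name raises with the row number.
    """
    records: dict[str, PathwayRecord] = {}
    if format == "tsv":
        with open(path, encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            for rownum, row in enumerate(reader, start=2):  # 1 is the header
                rec = _pathway_from_fields(
                    (row.get("id") or "").strip(),
                    (row.get("source") or "").strip(),
                    (row.get("name") or "").strip(),
                    _split_cell(row.get("aliases") or ""),
                    (row.get("definition") or "").strip(),
                    _split_cell(row.get("parents") or ""),
                    _split_cell(row.get("children") or ""),
                    where=f"row {rownum}",
                )
                records[rec.pathway_id] = rec
    elif format == "jsonl":
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                rec = _pathway_from_fields(
                    str(obj.get("id") or ""),
                    str(obj.get("source") or ""),
                    str(obj.get("name") or ""),
                    list(obj.get("aliases") or []),
                    obj.get("definition") or None,
                    list(obj.get("parents") or []),
                    list(obj.get("children") or []),
                    where=f"line {lineno}",
                )
                records[rec.pathway_id] = rec
    else:
        raise ValueError(f"unknown pathway format {format!r}; expected 'tsv' or 'jsonl'")
    return records


def write_pathway_records(records: Iterable[PathwayRecord], path: str | Path) -> None:
    """Write pathway records as TSV (inverse of :func:`read_pathway_records`)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_PATHWAY_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.pathway_id,
                    rec.source_db,
                    rec.names[0],
                    "|".join(rec.names[1:]),
                    rec.definition or "",
                    "|".join(rec.parent_ids),
                    "|".join(rec.child_ids),
                ]
            )


def read_mapping_table(path: str | Path) -> list[MappingRecord]:
    """Read a TSV of labelled (pathway, class) pairs.

    Columns: ``pathway_id``, ``class_id``, ``label`` (positive/negative),
    ``source``.  An unknown label raises.
    """
    records: list[MappingRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            rec = MappingRecord(
                pathway_id=row["pathway_id"],
                class_id=row["class_id"],
                label=row["label"],
                source=row.get("source") or "",
            )
            if rec.pair in seen:
                raise ValueError(f"duplicate pair {rec.pair} at row {rownum}")
            seen.add(rec.pair)
            records.append(rec)
    return records


def write_mapping_table(records: Iterable[MappingRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "class_id", "label", "source"])
        for rec in records:
            writer.writerow([rec.pathway_id, rec.class_id, rec.label, rec.source])


def write_predictions(predictions: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write predictions grouped by pathway, sorted by descending score.

    Pathway groups keep their first-appearance order; within a group rows are
    sorted by descending score (ties by class id), and ranks are rewritten to
    1..k to keep the rank/score invariant after regrouping.
    """
    groups: dict[str, list[PredictionRecord]] = {}
    for pred in predictions:
        groups.setdefault(pred.pathway_id, []).append(pred)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "class_id", "score", "rank"])
        for pathway_id, preds in groups.items():
            preds.sort(key=lambda p: (-p.score, p.class_id))
            for rank, pred in enumerate(preds, start=1):
                writer.writerow([pathway_id, pred.class_id, repr(pred.score), rank])


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            records.append(
                PredictionRecord(
                    pathway_id=row["pathway_id"],
                    class_id=row["class_id"],
                    score=float(row["score"]),
                    rank=int(row["rank"]),
                )
            )
    return records


def read_curation_labels(path: str | Path) -> list["CurationLabel"]:
    """TSV of curator grades: pathway_id, class_id, label (yes/related/no)."""
    from .types import CurationLabel

    labels: list[CurationLabel] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            labels.append(
                CurationLabel(row["pathway_id"], row["class_id"], row["label"])
            )
    return labels


def write_curation_labels(labels: Iterable["CurationLabel"], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "class_id", "label"])
        for lab in labels:
            writer.writerow([lab.pathway_id, lab.class_id, lab.label])


def read_text_pair_table(path: str | Path, source: str = "go_mesh") -> list["TrainingPair"]:
    """Generic labelled text-bundle pairs (e.g. GO/MeSH distant supervision).

    Columns: a_id, b_id, a_name, b_name, label, and optional a_def, b_def.
    """
    from .types import TrainingPair

    pairs: list[TrainingPair] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            pairs.append(
                TrainingPair(
                    a_id=row["a_id"],
                    b_id=row["b_id"],
                    a_name=row["a_name"],
                    b_name=row["b_name"],
                    label=row["label"],
                    source=row.get("source") or source,
                    a_def=row.get("a_def") or None,
                    b_def=row.get("b_def") or None,
                )
            )
    return pairs


def build_string_representation(
    entity: OntologyClass | PathwayRecord,
    context: Mapping[str, OntologyClass] | Mapping[str, PathwayRecord],
) -> str:
    """Concatenate an entity's names, definition and direct relatives' names.

    Segment order is fixed — names, definition, parent names, child names,
    space-joined — so tokenisation and idf weighting are reproducible.  For
    ontology classes both subclass and part-of parents contribute.  Relative
    ids that do not resolve in ``context`` are skipped with a logged warning.
    """
    if isinstance(entity, OntologyClass):
        names = entity.names
        parent_ids = [*entity.subclass_parents, *entity.part_of_parents]
        child_ids = entity.children
    else:
        names = entity.names
        parent_ids = entity.parent_ids
        child_ids = entity.child_ids

    pieces: list[str] = list(names)
    if entity.definition:
        pieces.append(entity.definition)
    for relative_id in [*parent_ids, *child_ids]:
        relative = context.get(relative_id)
        if relative is None:
            logger.warning(
                "unresolvable relative id %r for entity %r", relative_id, entity
            )
            continue
        pieces.append(relative.names[0] if isinstance(relative, PathwayRecord) else relative.name)
    return " ".join(pieces)
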