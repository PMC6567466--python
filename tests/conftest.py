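import pytest

from pwmap.types import MappingRecord, OntologyClass, PathwayRecord


@pytest.fixture
def tiny_ontology() -> dict[str, OntologyClass]:
    """Three classes: root, one child with synonyms/definition, one sibling."""
    root = OntologyClass("PW:0000001", "pathway")
    apoptosis = OntologyClass(
        "PW:0000009",
        "apoptotic cell death pathway",
        aliases=["apoptosis pathway"],
        definition="a programmed cell death pathway",
        subclass_parents=["PW:0000001"],
    )
    signaling = OntologyClass(
        "PW:0000050",
        "signaling pathway",
        subclass_parents=["PW:0000001"],
    )
    root.children = ["PW:0000009", "PW:0000050"]
    return {c.class_id: c for c in (root, apoptosis, signaling)}


@pytest.fixture
def tiny_db() -> dict[str, PathwayRecord]:
    records = [
        PathwayRecord(
            "R:1",
            "reactome",
            ["apoptosis", "programmed cell death"],
            definition="a cell death process",
        ),
        PathwayRecord("R:2", "reactome", ["signal transduction"]),
        PathwayRecord("R:3", "reactome", ["glycolysis"], child_ids=["R:1"]),
    ]
    return {r.pathway_id: r for r in records}


@pytest.fixture
def tiny_positives() -> list[MappingRecord]:
    return [
        MappingRecord("R:1", "PW:0000009", "positive", "pw_existing"),
        MappingRecord("R:2", "PW:0000050", "positive", "pw_existing"),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """Low-noise corpus shared by the slower integration tests."""
    from pwmap.synthetic import NoiseConfig, make_corpus

    return make_corpus(
        n_classes=40,
        pathways_per_class=2,
        noise=NoiseConfig(synonym_rate=0.2, dropout_rate=0.1, typo_rate=0.05,
                          paraphrase_rate=0.2),
        seed=7,
    )
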