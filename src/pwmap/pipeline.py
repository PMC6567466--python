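"""End-to-end orchestration: training-data assembly, bootstrapping, matcher
training, prediction and evaluation for one corpus.

This is the programmatic counterpart of the command-line subcommands and
the driver used by the synthetic-corpus studies: given an ontology, a
*source* database with curated mappings and a *target* database to map, it
runs both the bag-of-words baseline and the neural pipeline and reports the
curator-facing metrics for each.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

from . import bootstrap as bt
from . import lexical as lx
from .evaluate import evaluate_predictions
from .neural import (
    DefinitionMatcher,
    NameMatcher,
    split_train_dev,
    train_matcher,
)
from .predict import (
    DEFAULT_DEF_WEIGHT,
    DEFAULT_NAME_WEIGHT,
    DEFAULT_OUTPUT_THRESHOLD,
    predict_all,
)
from .synthetic import SyntheticCorpus, make_curation_labels
from .training_data import (
    TrainingSet,
    assemble_training_set,
    sample_all_negatives,
)
from .types import (
    POSITIVE,
    MappingRecord,
    OntologyClass,
    PathwayRecord,
    PredictionRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline, defaulting to the study conditions:
    top-20 blocking, n-grams {3,4,5}, 0.25% bootstrap tails over 10
    iterations, 90/10 split, 0.75/0.25 score weights, output threshold 0.25.
    """

    k: int = lx.DEFAULT_TOP_K
    ngram_sizes: frozenset[int] = lx.DEFAULT_NGRAM_SIZES
    n_easy: int = 2
    n_hard: int = 2
    bootstrap_frac: float = bt.BOOTSTRAP_FRACTION
    bootstrap_iters: int = bt.BOOTSTRAP_ITERATIONS
    dev_frac: float = 0.10
    w_name: float = DEFAULT_NAME_WEIGHT
    w_def: float = DEFAULT_DEF_WEIGHT
    output_threshold: float = DEFAULT_OUTPUT_THRESHOLD
    name_epochs: int = 30
    def_epochs: int = 15
    lr: float = 1e-3
    batch_size: int = 32
    lstm_hidden: int = 100
    decision_hidden: int = 128


@dataclass
class PipelineResult:
    training: TrainingSet
    bootstrapped: TrainingSet
    name_matcher: NameMatcher
    def_matcher: DefinitionMatcher
    bow_threshold: float
    bow_predictions: list[PredictionRecord]
    nn_predictions: list[PredictionRecord]
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    bootstrap_positive_accuracy: float | None = None


def _representations(
    ontology: Mapping[str, OntologyClass],
    source: Mapping[str, PathwayRecord],
    target: Mapping[str, PathwayRecord],
    ngram_sizes: frozenset[int],
) -> tuple[dict, dict, dict, lx.IdfTable]:
    from .corpus_io import build_string_representation

    docs: list[str] = []
    for entities in (ontology, source, target):
        docs.extend(build_string_representation(e, entities) for e in entities.values())
    idf = lx.build_idf(docs, ngram_sizes)
    class_tokens = lx.entity_token_sets(ontology, ngram_sizes=ngram_sizes)
    source_tokens = lx.entity_token_sets(source, ngram_sizes=ngram_sizes)
    target_tokens = lx.entity_token_sets(target, ngram_sizes=ngram_sizes)
    return class_tokens, source_tokens, target_tokens, idf


def run_pipeline(
    corpus: SyntheticCorpus,
    seed: int = 0,
    config: PipelineConfig | None = None,
    evaluate: bool = True,
) -> PipelineResult:
    """Run baseline + neural pipelines on a corpus and evaluate both.

    Training positives are the source database's curated mappings;
    negatives are 2 easy + 2 hard per class; the bootstrap rounds harvest
    pairs from the target database.  Metrics use simulated curator grades
    derived from the held-out target truth.
    """
    cfg = config or PipelineConfig()
    ontology = corpus.ontology
    source = corpus.databases["source"]
    target = corpus.databases["target"]

    class_tokens, source_tokens, target_tokens, idf = _representations(
        ontology, source, target, cfg.ngram_sizes
    )
    class_selector = lx.CandidateSelector(class_tokens, idf)
    reverse_selector = lx.CandidateSelector(source_tokens, idf)

    positives = [
        MappingRecord(pid, cid, POSITIVE, source="pw_existing")
        for pid, cid in corpus.truth["source"]
    ]
    negatives = sample_all_negatives(
        ontology,
        source,
        class_tokens,
        reverse_selector,
        positives,
        n_easy=cfg.n_easy,
        n_hard=cfg.n_hard,
        seed=seed,
    )
    training = assemble_training_set(positives, negatives, source, ontology)
    logger.info("initial training set: %d pairs", len(training.pairs))

    bootstrapped = bt.run_bootstrap(
        training,
        target,
        ontology,
        class_selector,
        target_tokens,
        iters=cfg.bootstrap_iters,
        frac=cfg.bootstrap_frac,
        k=cfg.k,
        seed=seed,
    )

    train_set, dev_set = split_train_dev(bootstrapped, cfg.dev_frac, seed=seed)
    name_matcher = NameMatcher(
        corpus.embeddings, decision_hidden=cfg.decision_hidden, seed=seed
    )
    name_matcher, _ = train_matcher(
        name_matcher,
        train_set,
        dev_set,
        epochs=cfg.name_epochs,
        lr=cfg.lr,
        batch_size=cfg.batch_size,
        seed=seed,
    )
    def_matcher = DefinitionMatcher(
        corpus.embeddings,
        hidden=cfg.lstm_hidden,
        decision_hidden=cfg.decision_hidden,
        seed=seed,
    )
    def_matcher, _ = train_matcher(
        def_matcher,
        train_set,
        dev_set,
        epochs=cfg.def_epochs,
        lr=cfg.lr,
        batch_size=cfg.batch_size,
        seed=seed,
    )

    nn_predictions = predict_all(
        target,
        ontology,
        class_selector,
        target_tokens,
        name_matcher,
        def_matcher,
        threshold=cfg.output_threshold,
        k=cfg.k,
        w_name=cfg.w_name,
        w_def=cfg.w_def,
    )

    # Baseline: threshold fitted on the labelled training pairs' scores.
    scored = lx.score_mapping_records(
        positives + negatives, source_tokens, class_tokens, idf
    )
    bow_threshold = lx.fit_bow_threshold(scored)
    bow_predictions: list[PredictionRecord] = []
    for pid, pathway in target.items():
        bow_predictions.extend(
            lx.bow_predict(pathway, target_tokens[pid], class_tokens, idf, bow_threshold)
        )

    result = PipelineResult(
        training=training,
        bootstrapped=bootstrapped,
        name_matcher=name_matcher,
        def_matcher=def_matcher,
        bow_threshold=bow_threshold,
        bow_predictions=bow_predictions,
        nn_predictions=nn_predictions,
    )

    boot_pos = [
        p for p in bootstrapped.pairs if p.source == "bootstrap" and p.label == POSITIVE
    ]
    if boot_pos:
        truth_pairs = set(corpus.truth["target"])
        result.bootstrap_positive_accuracy = sum(
            1 for p in boot_pos if p.pair in truth_pairs
        ) / len(boot_pos)

    if evaluate:
        truth_map = corpus.truth_map("target")
        universe = list(target)
        for model_name, preds in (("bow", bow_predictions), ("nn", nn_predictions)):
            labels = {
                (lab.pathway_id, lab.class_id): lab.label
                for lab in make_curation_labels(preds, truth_map, ontology)
            }
            result.metrics[model_name] = evaluate_predictions(preds, labels, universe)
            logger.info("%s metrics: %s", model_name, result.metrics[model_name])
    return result
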