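"""End-to-end pipeline: tag -> DF matrix -> signal metrics -> issue map.

Two entry modes:

* corpus mode — a JSONL corpus of tokenized documents is tagged against the
  ontology terminology, binned, and analyzed;
* matrix mode — a precomputed DF matrix CSV is analyzed directly, which
  supports reanalysis of published DF tables when the underlying corpus is
  unavailable.

Each stage logs row counts; outputs are plain CSV so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .coverage import ConceptMention, coverage_table, map_concepts
from .kim import KimResult, build_kim_from_metrics, classify_signals
from .metrics import TimeWeightConfig, compute_signal_metrics
from .ontology import OntologySet, load_ontology
from .synthetic import CorpusSpec, PlantedTruth, generate_corpus, recovery_report
from .tagging import (KeywordPeriodMatrix, PeriodBinning, build_df_matrix,
                      read_corpus_jsonl, select_top_keywords)

logger = logging.getLogger("ontosig")


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run."""

    class_file: Path
    term_file: Path
    output_dir: Path
    relation_file: Path | None = None
    eav_file: Path | None = None
    corpus_file: Path | None = None
    matrix_file: Path | None = None
    mentions_file: Path | None = None
    window_start: dt.date = dt.date(2011, 1, 1)
    window_end: dt.date = dt.date(2015, 6, 30)
    top_k: int = 17
    tw: float = 0.05
    candidate_concepts: list[str] = field(default_factory=list)
    assume_constant_nn: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 2:
            raise ValueError("top_k must be at least 2 (an issue map needs >= 2 keywords)")
        binning = PeriodBinning.yearly(self.window_start, self.window_end)
        TimeWeightConfig(self.tw).validate_for(binning.n)
        if (self.corpus_file is None) == (self.matrix_file is None):
            raise ValueError("exactly one of corpus_file or matrix_file is required")


def run_pipeline(cfg: PipelineConfig, ontology: OntologySet | None = None) -> dict[str, Path]:
    """Execute the configured stages and write the artifact bundle.

    Returns paths of the written artifacts (metrics.csv, kim.csv, and
    coverage.csv when a mentions file is given).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if ontology is None:
        ontology = load_ontology(cfg.class_file, cfg.relation_file,
                                 cfg.eav_file, cfg.term_file)
    logger.info("ontology: %d classes, %d relations, %d terms",
                len(ontology.classes), len(ontology.relations), len(ontology.terms))

    binning = PeriodBinning.yearly(cfg.window_start, cfg.window_end)
    if cfg.corpus_file is not None:
        docs = read_corpus_jsonl(cfg.corpus_file)
        logger.info("corpus: %d documents", len(docs))
        candidates = cfg.candidate_concepts or _default_candidates(ontology)
        if cfg.top_k > len(candidates):
            raise ValueError(
                f"top_k={cfg.top_k} exceeds the {len(candidates)} candidate concepts")
        full = build_df_matrix(ontology, docs, binning, candidates)
        keywords = select_top_keywords(full, cfg.top_k)
        matrix = full.subset(keywords)
    else:
        matrix = KeywordPeriodMatrix.from_csv(
            cfg.matrix_file, assume_constant_nn=cfg.assume_constant_nn)
        matrix.labels = {k: ontology.classes[k].label if k in ontology.classes else k
                         for k in matrix.keywords}
    logger.info("DF matrix: %d keywords x %d periods (NN total %d)",
                len(matrix.keywords), matrix.n, int(matrix.nn.sum()))

    metrics = compute_signal_metrics(matrix, TimeWeightConfig(cfg.tw))
    metrics_path = out / "metrics.csv"
    metrics.rename_axis("keyword").to_csv(metrics_path)
    artifacts["metrics"] = metrics_path
    logger.info("metrics: %d rows -> %s", len(metrics), metrics_path)

    kim = build_kim_from_metrics(metrics)
    kim_path = out / "kim.csv"
    kim.to_csv(kim_path)
    artifacts["kim"] = kim_path
    grouped = classify_signals(kim)
    logger.info("kim: medians (%.3f, %.4f); %s -> %s",
                kim.x_median, kim.y_median,
                {k: len(v) for k, v in grouped.items()}, kim_path)

    if cfg.mentions_file is not None:
        frame = pd.read_csv(cfg.mentions_file, dtype=str)
        mentions = [ConceptMention(r.concept_label, r.group)
                    for r in frame.itertuples(index=False)]
        table = coverage_table(map_concepts(ontology, mentions))
        coverage_path = out / "coverage.csv"
        table.to_frame().to_csv(coverage_path)
        artifacts["coverage"] = coverage_path
        logger.info("coverage: %d mentions -> %s", len(mentions), coverage_path)

    return artifacts


def _default_candidates(ontology: OntologySet) -> list[str]:
    """Leaf classes, the natural candidate keywords for tagging."""
    return sorted(c for c in ontology.classes if not ontology.children(c))


def run_synthetic_recovery(
    ontology: OntologySet,
    spec: CorpusSpec,
    tw: float = 0.05,
) -> tuple[KimResult, PlantedTruth, pd.DataFrame, float]:
    """Generate a planted corpus, run the full pipeline, and score how well
    the issue-map quadrants recover the planted archetypes."""
    docs, truth = generate_corpus(ontology, spec)
    matrix = build_df_matrix(ontology, docs, spec.binning, list(spec.keywords))
    metrics = compute_signal_metrics(matrix, TimeWeightConfig(tw))
    kim = build_kim_from_metrics(metrics)
    confusion, accuracy = recovery_report(truth, kim)
    return kim, truth, confusion, accuracy
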