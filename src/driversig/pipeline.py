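"""Two-stage orchestration: driver-signal characterization, then end-to-end training.

Stage 1 (:func:`run_characterize`) builds the high-confidence network, runs
RWR from the driver seeds, selects the pathway signature by preranked GSEA on
the propagation ranking, and scores per-cell pathway activity with ssGSEA.

Stage 2 (:func:`run_full`) assembles per-pair features, splits the pair table,
trains the joint autoencoder-regressor end to end, and evaluates on the test
partition.  Both stages log per-step record counts and return everything the
CLI needs to write artifacts and a reproducibility manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentRecord,
    PathwaySignature,
    RankedList,
    activity_matrix,
    gsea,
    select_signature,
)
from .evaluation import MetricReport, SplitResult, SplitSpec, evaluate_predictions, split_pairs
from .neural_model import (
    AutoencoderSpec,
    Batch,
    DrugResponseModel,
    FeatureSet,
    TrainConfig,
    train_end_to_end,
)
from .ppi_propagation import (
    PropagationScores,
    filter_edges,
    largest_connected_component,
    make_seed_vector,
    normalize_columns,
    propagate,
)

__all__ = [
    "CharacterizationResult",
    "FullRunResult",
    "run_characterize",
    "default_ae_spec",
    "run_full",
]


@dataclass
class CharacterizationResult:
    network: object
    scores: PropagationScores
    ranking: RankedList
    records: list[EnrichmentRecord]
    signature: PathwaySignature
    activity: pd.DataFrame
    log: dict = field(default_factory=dict)


def run_characterize(
    edge_records: Iterable[tuple[str, str, str]],
    driver_genes: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    expression: pd.DataFrame,
    min_sources: int = 2,
    beta: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    exponent: float = 0.25,
    n_perm: int = 1000,
    es_min: float = 0.0,
    fdr_max: float = 0.2,
    alpha: float = 0.25,
    normalize_activity: bool = True,
    seed: int = 0,
) -> CharacterizationResult:
    """filter edges -> largest component -> RWR -> GSEA -> signature -> ssGSEA.

    The GSEA weighting exponent defaults to 0.25 here (not the generic 1):
    the propagation vector is a probability distribution whose mass sits on
    the seeds, and undamped weight-proportional increments would saturate the
    enrichment statistic for essentially every gene set.  Activity scores are
    min-max normalized by default (the usual ssGSEA convention), keeping the
    expression embedding on the same scale as the bottleneck embeddings.
    """
    stage = "filter_edges"
    try:
        net = filter_edges(edge_records, min_sources=min_sources)
        n_raw_nodes, n_raw_edges = net.n_nodes, net.n_edges
        stage = "largest_connected_component"
        net = largest_connected_component(net)
        stage = "propagation"
        T = normalize_columns(net)
        c0 = make_seed_vector(net, driver_genes)
        scores = propagate(T, c0, beta=beta, tol=tol, max_iter=max_iter)
        ranking = RankedList.from_scores(pd.Series(scores.values, index=net.node_ids))
        stage = "gsea"
        records = gsea(ranking, collection, exponent=exponent, n_perm=n_perm, seed=seed)
        stage = "select_signature"
        signature = select_signature(records, es_min=es_min, fdr_max=fdr_max)
        stage = "activity_matrix"
        activity = activity_matrix(
            expression, signature, collection, alpha=alpha,
            normalize=normalize_activity,
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    log = {
        "edges_kept": n_raw_edges,
        "nodes_after_filter": n_raw_nodes,
        "nodes_in_component": net.n_nodes,
        "edges_in_component": net.n_edges,
        "seeds_mapped": c0.n_mapped,
        "seeds_unmapped": c0.n_unmapped,
        "rwr_iterations": scores.iterations,
        "rwr_converged": scores.converged,
        "pathways_tested": len(records),
        "pathways_selected": len(signature),
    }
    return CharacterizationResult(net, scores, ranking, records, signature, activity, log)


def default_ae_spec(input_dim: int) -> AutoencoderSpec:
    """Width heuristic scaling the reference (300, 100, 30) stack to the input.

    For a 1024-bit fingerprint this reproduces (300, 100, 30); for small
    synthetic feature blocks the widths shrink proportionally.
    """
    h1 = min(300, max(3, round(0.8 * input_dim)))
    h2 = min(100, max(2, round(0.4 * input_dim)))
    b = min(30, max(1, round(0.2 * input_dim)))
    h1 = min(h1, input_dim - 1)
    h2 = min(h2, h1)
    b = min(b, h2)
    return AutoencoderSpec(input_dim, h1, h2, b)


@dataclass
class FullRunResult:
    model: DrugResponseModel
    report: MetricReport
    split: SplitResult
    predictions: pd.DataFrame
    log: dict = field(default_factory=dict)


def run_full(
    pairs: pd.DataFrame,
    features: FeatureSet,
    signature: list[str],
    split_spec: SplitSpec,
    config: TrainConfig,
    mut_spec: AutoencoderSpec | None = None,
    drug_spec: AutoencoderSpec | None = None,
) -> FullRunResult:
    """Split -> train end-to-end -> evaluate on the test partition."""
    stage = "feature_coverage"
    try:
        usable = pairs.loc[features.coverage(pairs)].reset_index(drop=True)
        if usable.empty:
            raise ValueError("no pair has complete features")
        stage = "split"
        split = split_pairs(usable, split_spec)
        stage = "feature_assembly"
        if mut_spec is None:
            mut_spec = default_ae_spec(features.mutations.shape[0])
        if drug_spec is None:
            drug_spec = default_ae_spec(features.fingerprints.shape[0])
        batches = {
            name: features.batch(part, signature=signature)
            for name, part in zip(("train", "val", "test"), split.partitions)
        }
        stage = "train"
        model = DrugResponseModel.build(signature, mut_spec, drug_spec, seed=config.seed)
        train_end_to_end(model, batches["train"], batches["val"], config)
        stage = "evaluate"
        test = batches["test"]
        pred = model.predict(test.a, test.r_c, test.r_d)
        report = evaluate_predictions(pred, test.s)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    predictions = split.test.copy()
    predictions["s_pred"] = pred
    log = {
        "pairs_usable": len(usable),
        "pairs_dropped_missing_features": int(len(pairs) - len(usable)),
        "split_sizes": {k: len(v) for k, v in zip(("train", "val", "test"), split.partitions)},
        "pairs_discarded_cross_partition": split.n_discarded,
        "epochs_run": len(model.history),
        "best_epoch": next((h["epoch"] for h in model.history if h.get("best")), None),
        "test_metrics": report.as_dict(),
    }
    return FullRunResult(model, report, split, predictions, log)
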