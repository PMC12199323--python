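"""Model interpretation: Integrated Gradients and embedding annotation.

Attribution is computed with respect to the regressor's input layer — the
concatenation of pathway activities and the two bottleneck embeddings — so
each attribution column is directly a pathway or an embedding dimension.
Integrated Gradients approximates the path integral from a baseline x' to the
input x with a midpoint Riemann sum:

    IG_i(x) = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF/dx_i (x' + ((k-1/2)/m)(x - x'))

which satisfies the completeness axiom sum_i IG_i = F(x) - F(x') in the limit
(exactly, at any m, for affine F); the midpoint rule converges quadratically
on smooth segments, where the one-sided Riemann sums are only first order.  Negative IG scores mean the feature lowers
the predicted LN IC50, i.e. increases sensitivity.

Mutation-embedding dimensions are annotated by correlating each dimension with
every gene's expression across samples, ranking genes by that correlation, and
running preranked GSEA on the ranking; pathways below an FDR cutoff become the
dimension's annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import RankedList, gsea
from .neural_model import DrugResponseModel

__all__ = [
    "integrated_gradients",
    "attribute_model",
    "global_ig",
    "ig_score_table",
    "DimensionAnnotation",
    "annotate_dimensions",
    "group_cells_by_sensitivity",
]

GradFn = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


def integrated_gradients(
    grad_fn: GradFn,
    inputs: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
) -> np.ndarray:
    """Sample x feature attribution matrix for a scalar-output model.

    ``grad_fn(X)`` must return ``(values, gradients)`` for a batch of inputs,
    gradients being dF/dx per sample.  The baseline defaults to all zeros.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if baseline is None:
        baseline = np.zeros(x.shape[1])
    base = np.asarray(baseline, dtype=np.float64).ravel()
    if base.shape[0] != x.shape[1]:
        raise ValueError("baseline shape does not match input features")
    diff = x - base
    n, d = x.shape
    # evaluate all interpolation points in one batch: (steps * n, d)
    alphas = ((np.arange(steps) + 0.5) / steps)[:, None, None]
    points = (base + alphas * diff).reshape(steps * n, d)
    _, grads = grad_fn(points)
    if not np.all(np.isfinite(grads)):
        bad = np.nonzero(~np.isfinite(grads).all(axis=1))[0]
        raise ValueError(f"non-finite gradients at interpolation rows {bad[:5].tolist()}")
    avg_grad = grads.reshape(steps, n, d).mean(axis=0)
    return diff * avg_grad


def attribute_model(
    model: DrugResponseModel,
    a: np.ndarray,
    r_c: np.ndarray,
    r_d: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
) -> pd.DataFrame:
    """IG attributions over the regressor's input (activities + embeddings)."""
    out = model.forward(a, r_c, r_d, training=False)
    attr = integrated_gradients(model.predictor.gradient, out["h"], baseline, steps)
    b_c = model.mut_ae.spec.bottleneck
    b_d = model.drug_ae.spec.bottleneck
    cols = (
        list(model.signature)
        + [f"mut_dim_{i}" for i in range(b_c)]
        + [f"drug_dim_{i}" for i in range(b_d)]
    )
    return pd.DataFrame(attr, columns=cols)


def global_ig(attributions: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Per-feature mean attribution across samples (the IG score).

    Negative scores push predicted LN IC50 down (greater sensitivity).
    """
    arr = np.asarray(attributions, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("attribution matrix must have at least one sample row")
    means = arr.mean(axis=0)
    if isinstance(attributions, pd.DataFrame):
        return pd.Series(means, index=attributions.columns, name="ig_score")
    return means


def ig_score_table(attributions: pd.DataFrame) -> pd.DataFrame:
    """IG scores with their |score| ranks (1 = most important)."""
    scores = global_ig(attributions)
    table = pd.DataFrame({"feature": scores.index, "ig_score": scores.to_numpy()})
    table["abs_rank"] = (
        table["ig_score"].abs().rank(ascending=False, method="first").astype(int)
    )
    return table.sort_values("abs_rank").reset_index(drop=True)


@dataclass
class DimensionAnnotation:
    """Pathway annotations per embedding dimension, plus skipped dimensions."""

    annotations: dict[int, list[tuple[str, float, int]]]  # dim -> (pathway, fdr, sign)
    skipped_dimensions: list[int] = field(default_factory=list)

    def annotated(self) -> list[int]:
        return [d for d, paths in self.annotations.items() if paths]


def annotate_dimensions(
    embedding: np.ndarray | pd.DataFrame,
    expression: pd.DataFrame,
    collection: Mapping[str, Iterable[str]],
    fdr_max: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> DimensionAnnotation:
    """Correlation-GSEA annotation of embedding dimensions.

    ``embedding`` is dimension x sample, ``expression`` gene x sample over the
    same sample columns.  For each dimension, genes are ranked by their Pearson
    correlation with the dimension across samples and preranked GSEA is run on
    that ranking; pathways with FDR below ``fdr_max`` (positive or negative ES)
    are retained with the sign of their ES.  Constant dimensions are skipped
    and reported; constant gene rows are excluded from the ranking.
    """
    E = np.atleast_2d(np.asarray(
        embedding.to_numpy() if isinstance(embedding, pd.DataFrame) else embedding,
        dtype=float,
    ))
    G = expression.to_numpy(dtype=float)
    if E.shape[1] != G.shape[1]:
        raise ValueError("embedding and expression must share sample columns")
    if E.shape[1] < 3:
        raise ValueError("need at least 3 shared samples")

    gene_sd = G.std(axis=1)
    usable_genes = gene_sd > 0
    Gc = G[usable_genes] - G[usable_genes].mean(axis=1, keepdims=True)
    Gn = Gc / np.linalg.norm(Gc, axis=1, keepdims=True)
    gene_ids = expression.index.to_numpy(dtype=object)[usable_genes]

    annotations: dict[int, list[tuple[str, float, int]]] = {}
    skipped: list[int] = []
    for dim in range(E.shape[0]):
        row = E[dim]
        if row.std() == 0:
            skipped.append(dim)
            continue
        rc = row - row.mean()
        corr = Gn @ (rc / np.linalg.norm(rc))
        ranked = RankedList.from_scores(pd.Series(corr, index=gene_ids))
        records = gsea(ranked, collection, exponent=exponent, n_perm=n_perm,
                       seed=seed + dim)
        hits = [
            (r.set_name, r.fdr, 1 if r.es > 0 else -1)
            for r in records
            if r.fdr < fdr_max
        ]
        hits.sort(key=lambda t: (t[1], t[0]))
        annotations[dim] = hits
    return DimensionAnnotation(annotations, skipped)


def group_cells_by_sensitivity(pairs: pd.DataFrame) -> pd.Series:
    """Label cells sensitive/insensitive by the first quartile of mean LN IC50.

    Each cell's LN IC50 is averaged over its drugs; cells at or below the 25th
    percentile of these means are "sensitive", the rest "insensitive".
    """
    if not {"cell_id", "ln_ic50"}.issubset(pairs.columns):
        raise ValueError("pair table must have cell_id and ln_ic50 columns")
    means = pairs.groupby("cell_id")["ln_ic50"].mean()
    if len(means) < 4:
        raise ValueError("need at least 4 cells")
    if np.all(means.to_numpy() == means.iloc[0]):
        raise ValueError("all per-cell means identical: quartile undefined")
    tau = float(np.percentile(means.to_numpy(), 25))
    labels = np.where(means.to_numpy() <= tau, "sensitive", "insensitive")
    return pd.Series(labels, index=means.index, name="sensitivity_group")
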