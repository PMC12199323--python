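"""Preranked GSEA over the propagation ranking and ssGSEA pathway activity.

Two statistics live here:

* :func:`enrichment_score` / :func:`gsea` — the weighted Kolmogorov-Smirnov
  enrichment score of a gene set against a ranked gene list, with an empirical
  permutation null (random gene sets of matched size) and Benjamini-Hochberg
  FDR.  Pathways with ES > 0 and FDR below a cutoff form the driver-signal
  signature (:func:`select_signature`).
* :func:`ssgsea_sample` / :func:`activity_matrix` — the per-sample,
  rank-weighted enrichment statistic of Barbie et al., used as the pathway
  activity of each cell line.  It depends only on the within-sample expression
  ranks, so it is exactly invariant under monotone transforms of a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "EnrichmentRecord",
    "PathwaySignature",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "gsea",
    "select_signature",
    "ssgsea_sample",
    "activity_matrix",
]


@dataclass
class RankedList:
    """Genes ordered by non-increasing weight; identifiers unique."""

    genes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.genes.shape != self.weights.shape or self.genes.ndim != 1:
            raise ValueError("genes and weights must be equal-length 1-D arrays")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValueError("duplicate gene identifiers in ranked list")
        if np.any(np.diff(self.weights) > 0):
            raise ValueError("weights must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float] | pd.Series) -> "RankedList":
        """Stable descending sort of a gene -> score mapping (ties keep input order)."""
        s = pd.Series(scores, dtype=float)
        order = np.argsort(-s.to_numpy(), kind="stable")
        return cls(s.index.to_numpy(dtype=object)[order], s.to_numpy()[order])


@dataclass
class EnrichmentRecord:
    set_name: str
    es: float
    p_value: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    set_size: int = 0


@dataclass
class PathwaySignature:
    """Pathways passing ES/FDR selection, ordered by ascending FDR then |ES|."""

    records: list[EnrichmentRecord]

    @property
    def names(self) -> list[str]:
        return [r.set_name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one gene set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln + 1}: fewer than 3 fields")
            name = parts[0].strip()
            members = {g.strip() for g in parts[2:] if g.strip()}
            if not name or not members:
                raise ValueError(f"GMT line {ln + 1}: empty name or member list")
            if name in sets:
                raise ValueError(f"GMT line {ln + 1}: duplicate set name {name!r}")
            sets[name] = members
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(path: str | Path, collection: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def _es_from_hits(
    hits: np.ndarray, weights: np.ndarray, exponent: float
) -> tuple[float, int]:
    """Signed-max-deviation ES and peak index from a boolean hit mask.

    The running sum increments by |w|^exponent (normalized over hits) at hits
    and decrements by 1/(N - n_hits) at misses.
    """
    n = hits.size
    n_hits = int(hits.sum())
    n_miss = n - n_hits
    if n_miss == 0:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(weights) ** exponent
    hit_total = w[hits].sum()
    if hit_total == 0.0:
        raise ValueError("all hit weights are zero under the given exponent")
    step = np.where(hits, w / hit_total, -1.0 / n_miss)
    running = np.cumsum(step)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], exponent: float = 1.0
) -> tuple[float, list[str]]:
    """Weighted KS enrichment score and leading-edge subset.

    For ES > 0 the leading edge is the set members at or before the running-sum
    peak; for ES < 0 those at or after the trough.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                       count=len(ranked))
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    es, peak = _es_from_hits(hits, ranked.weights, exponent)
    if es >= 0:
        le_mask = hits & (np.arange(len(ranked)) <= peak)
    else:
        le_mask = hits & (np.arange(len(ranked)) >= peak)
    return es, ranked.genes[le_mask].tolist()


def _null_es(
    n: int,
    set_size: int,
    weights: np.ndarray,
    exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES distribution of random gene sets of matched size (vectorized)."""
    w = np.abs(weights) ** exponent
    n_miss = n - set_size
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    hit_tot = (hits * w).sum(axis=1, keepdims=True)
    hit_tot[hit_tot == 0.0] = np.inf  # degenerate perm: no positive hit weight
    step = np.where(hits, w / hit_tot, -1.0 / n_miss)
    running = np.cumsum(step, axis=1)
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def gsea(
    ranked: RankedList,
    collection: Mapping[str, Iterable[str]],
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentRecord]:
    """Preranked GSEA over a gene-set collection.

    The null for each set is the ES of ``n_perm`` random gene sets of matched
    size drawn from the ranked universe.  Empirical p-values are one-sided
    within the sign of the observed ES: for ES > 0,
    ``p = (1 + #{null >= ES, null >= 0}) / (1 + #{null >= 0})`` and mirrored
    for ES < 0, so that p is approximately uniform under the null.  FDR is
    Benjamini-Hochberg over the collection.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not collection:
        raise ValueError("gene-set collection is empty")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes.tolist())
    n = len(ranked)

    null_cache: dict[int, np.ndarray] = {}
    results: list[tuple[str, float, list[str], int, float]] = []
    for name, members in collection.items():
        size = len(set(members) & universe)
        if size == 0:
            warnings.warn(f"gene set {name!r} does not overlap the ranked list; skipped")
            continue
        es, le = enrichment_score(ranked, members, exponent)
        if size not in null_cache:
            null_cache[size] = _null_es(n, size, ranked.weights, exponent, n_perm, rng)
        null = null_cache[size]
        if es >= 0:
            pool = null[null >= 0]
            p = (1.0 + np.count_nonzero(pool >= es)) / (1.0 + pool.size)
        else:
            pool = null[null < 0]
            p = (1.0 + np.count_nonzero(pool <= es)) / (1.0 + pool.size)
        results.append((name, es, le, size, p))

    if not results:
        raise ValueError("no gene set overlaps the ranked list")
    pvals = np.array([r[4] for r in results])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentRecord(name, es, float(p), float(q), le, size)
        for (name, es, le, size, p), q in zip(results, fdr)
    ]


def select_signature(
    records: Sequence[EnrichmentRecord],
    es_min: float = 0.0,
    fdr_max: float = 0.2,
) -> PathwaySignature:
    """Retain records with es > es_min and fdr < fdr_max (both strict).

    Ordered by ascending FDR, then descending ES, then name.
    """
    if not records:
        raise ValueError("no enrichment records supplied")
    kept = [r for r in records if r.es > es_min and r.fdr < fdr_max]
    if not kept:
        raise ValueError(
            f"no pathway passes es > {es_min} and fdr < {fdr_max}; "
            "consider relaxing the thresholds"
        )
    kept.sort(key=lambda r: (r.fdr, -r.es, r.set_name))
    return PathwaySignature(kept)


def ssgsea_sample(
    expression: pd.Series, gene_set: Iterable[str], alpha: float = 0.25
) -> float:
    """Single-sample enrichment (Barbie-style) of one gene set in one sample.

    Genes are ordered by descending expression; the gene at descending
    position i (0-based) carries rank value N - i.  The statistic is the sum
    over all positions of P_hit(i) - P_miss(i), with hit weights rank^alpha
    normalized over the set's hits and misses weighted uniformly.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    values = expression.to_numpy(dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 genes")
    if np.all(values == values[0]):
        raise ValueError("constant expression column: ranks undefined")
    members = set(gene_set)
    order = np.argsort(-values, kind="stable")
    genes_sorted = expression.index.to_numpy(dtype=object)[order]
    hits = np.fromiter((g in members for g in genes_sorted), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the expressed genes")
    if n_hits == n:
        raise ValueError("gene set covers all genes: miss distribution undefined")
    rank_val = (n - np.arange(n)).astype(float)
    wh = np.where(hits, rank_val**alpha, 0.0)
    p_hit = np.cumsum(wh) / wh.sum()
    p_miss = np.cumsum(~hits) / float(n - n_hits)
    return float(np.sum(p_hit - p_miss))


def activity_matrix(
    expression: pd.DataFrame,
    signature: PathwaySignature | Mapping[str, Iterable[str]],
    collection: Mapping[str, Iterable[str]] | None = None,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Pathway x sample ssGSEA activity matrix.

    ``signature`` may be a :class:`PathwaySignature` (member sets then looked up
    in ``collection``) or a name -> gene-set mapping.  Row order follows the
    signature, column order the expression matrix.  With ``normalize=True`` the
    whole matrix is min-max rescaled to [0, 1] (off by default; scores are
    otherwise reported raw).
    """
    if expression.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    if isinstance(signature, PathwaySignature):
        if collection is None:
            raise ValueError("collection required to resolve signature pathway members")
        sets = {name: set(collection[name]) for name in signature.names}
    else:
        sets = {name: set(members) for name, members in signature.items()}

    expressed = set(expression.index)
    for name, members in sets.items():
        if not members & expressed:
            raise ValueError(f"pathway {name!r} has no expressed member genes")

    mat = np.empty((len(sets), expression.shape[1]))
    for j, col in enumerate(expression.columns):
        sample = expression[col]
        for i, (name, members) in enumerate(sets.items()):
            mat[i, j] = ssgsea_sample(sample, members, alpha)
    if normalize:
        lo, hi = mat.min(), mat.max()
        if hi > lo:
            mat = (mat - lo) / (hi - lo)
    return pd.DataFrame(mat, index=list(sets.keys()), columns=expression.columns)
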