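"""High-confidence protein-protein interaction network and random walk with restart.

The propagation stage scores every gene in a PPI network by its proximity to a
set of seed genes (cancer drivers).  Edges are kept only when supported by a
minimum number of distinct evidence sources, the largest connected component is
extracted, the binary adjacency ``P`` is column-normalized into a transition
matrix ``T``, and the walk

    c(t+1) = (1 - beta) * T @ c(t) + beta * c0

is iterated from the uniform seed distribution ``c0`` until the max-norm change
between successive iterates drops below ``tol``.  ``beta`` is the restart
probability controlling diffusion depth (default 0.9, i.e. shallow diffusion
that stays near the seeds).  The fixed point is the propagation score vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Network",
    "SeedVector",
    "PropagationScores",
    "filter_edges",
    "largest_connected_component",
    "normalize_columns",
    "make_seed_vector",
    "propagate",
    "read_edge_list",
    "write_scores",
]


@dataclass
class Network:
    """Undirected, unweighted gene network.

    ``adjacency`` is a dense square binary matrix aligned with ``node_ids``;
    symmetric with a zero diagonal.
    """

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.node_ids):
            raise ValueError("adjacency size does not match node_ids")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def to_edge_records(self, source: str = "network") -> list[tuple[str, str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return [(self.node_ids[a], self.node_ids[b], source) for a, b in zip(i, j)]


@dataclass
class SeedVector:
    """Initial restart distribution c0: uniform over mapped seeds, zero elsewhere."""

    values: np.ndarray
    n_mapped: int
    n_unmapped: int
    unmapped: list[str] = field(default_factory=list)


@dataclass
class PropagationScores:
    """Converged (or capped) RWR probability vector over network nodes."""

    values: np.ndarray
    iterations: int
    converged: bool


def _clean(gene: str) -> str:
    return str(gene).strip()


def filter_edges(
    edge_records: Iterable[tuple[str, str, str]], min_sources: int = 2
) -> Network:
    """Build a network from (geneA, geneB, source) records.

    An undirected edge is kept iff the unordered gene pair is observed under at
    least ``min_sources`` *distinct* source tags.  Self-pairs are discarded and
    duplicate (pair, source) records collapse to one observation.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    records = list(edge_records)
    if not records:
        raise ValueError("empty edge record list")

    pair_sources: dict[tuple[str, str], set[str]] = {}
    for idx, rec in enumerate(records):
        try:
            a, b, src = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge record at index {idx}: {rec!r}") from exc
        a, b, src = _clean(a), _clean(b), _clean(src)
        if not a or not b or not src:
            raise ValueError(f"malformed edge record at index {idx}: {rec!r}")
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        pair_sources.setdefault(key, set()).add(src)

    kept = [pair for pair, srcs in pair_sources.items() if len(srcs) >= min_sources]
    if not kept:
        raise ValueError(
            f"no edge supported by >= {min_sources} distinct sources"
        )
    nodes = sorted({g for pair in kept for g in pair})
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b in kept:
        adj[index[a], index[b]] = 1.0
        adj[index[b], index[a]] = 1.0
    return Network(nodes, adj)


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component; node order preserved.

    Equal-size components are resolved in favour of the one containing the
    lexicographically smallest node identifier, for determinism.
    """
    if net.n_nodes == 0:
        raise ValueError("network has no nodes")
    n_comp, labels = connected_components(
        csr_matrix(net.adjacency), directed=False
    )
    if n_comp == 1:
        return net
    sizes = np.bincount(labels, minlength=n_comp)
    # among max-size components pick the one whose smallest node id sorts first
    max_size = sizes.max()
    candidates = [c for c in range(n_comp) if sizes[c] == max_size]
    best = min(
        candidates,
        key=lambda c: min(net.node_ids[i] for i in np.nonzero(labels == c)[0]),
    )
    keep = np.nonzero(labels == best)[0]
    sub = net.adjacency[np.ix_(keep, keep)]
    return Network([net.node_ids[i] for i in keep], sub)


def normalize_columns(net: Network) -> np.ndarray:
    """Column-stochastic transition matrix T[i, j] = P[i, j] / degree(j)."""
    deg = net.degrees
    if np.any(deg == 0):
        bad = [net.node_ids[i] for i in np.nonzero(deg == 0)[0][:5]]
        raise ValueError(
            "zero-degree node(s) present (extract the largest connected "
            f"component first): {bad}"
        )
    return net.adjacency / deg[np.newaxis, :]


def make_seed_vector(net: Network, seed_genes: Iterable[str]) -> SeedVector:
    """Uniform probability 1/m over the m seed genes mapped into the network."""
    seeds = {_clean(g) for g in seed_genes if _clean(g)}
    if not seeds:
        raise ValueError("seed gene set is empty")
    index = {g: i for i, g in enumerate(net.node_ids)}
    mapped = sorted(seeds & index.keys())
    unmapped = sorted(seeds - index.keys())
    if not mapped:
        raise ValueError("no seed gene maps into the network")
    values = np.zeros(net.n_nodes)
    values[[index[g] for g in mapped]] = 1.0 / len(mapped)
    return SeedVector(values, len(mapped), len(unmapped), unmapped)


def propagate(
    T: np.ndarray,
    c0: SeedVector | np.ndarray,
    beta: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PropagationScores:
    """Iterate the RWR update to its fixed point.

    Stops when ``max |c(t+1) - c(t)| < tol`` or after ``max_iter`` updates; in
    the latter case the result is returned with ``converged=False``.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must be in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    T = np.asarray(T, dtype=float)
    col_sums = T.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-8):
        raise ValueError("transition matrix is not column-stochastic")
    c = np.asarray(c0.values if isinstance(c0, SeedVector) else c0, dtype=float).copy()
    start = c.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        c_next = (1.0 - beta) * (T @ c) + beta * start
        diff = np.max(np.abs(c_next - c))
        c = c_next
        if diff < tol:
            converged = True
            break
    return PropagationScores(c, iterations, converged)


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV edge list with columns geneA, geneB, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"geneA", "geneB", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    return list(df[["geneA", "geneB", "source"]].itertuples(index=False, name=None))


def write_scores(path: str | Path, net: Network, scores: PropagationScores) -> None:
    """Two-column TSV (gene, score), descending by score; ties by gene id."""
    df = pd.DataFrame({"gene": net.node_ids, "score": scores.values})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    df.to_csv(path, sep="\t", index=False)
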