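"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the input structure of a drug-sensitivity screen
without any downloads:

* a sparse undirected gene network with planted modules (denser within-module
  wiring, connected by construction),
* pathways that coincide with the network modules (plus random decoy sets), so
  propagation from planted drivers genuinely enriches the planted pathways,
* pathway-structured expression: per-cell latent module activities drive the
  expression of the module's genes plus Gaussian noise,
* Bernoulli driver-gene mutations with gene-specific rates, summarized into a
  per-cell mutation latent, and Bernoulli fingerprint bits summarized into a
  per-drug latent,
* LN IC50 generated as a noisy linear function of the driver-module activity,
  the mutation latent, the drug latent, and a small mutation x drug
  interaction.

All randomness flows from one master seed through named substreams (network,
expression, mutation, drugs, response), so components regenerate independently
and identically.  ``ground_truth`` retains every latent and weight needed to
recompute the noiseless responses exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import write_gmt, read_gmt
from .ppi_propagation import Network, filter_edges

__all__ = ["CohortSpec", "SyntheticCohort", "simulate_network", "simulate_cohort",
           "write_fixture", "read_fixture"]

_STREAMS = ("network", "expression", "mutation", "drugs", "response")


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings; the defaults define the reference study conditions."""

    n_genes: int = 500
    n_cells: int = 200
    n_drugs: int = 50
    n_pathways: int = 20            # planted pathways = network modules
    pathway_size: tuple[int, int] = (20, 30)
    n_decoy_pathways: int = 20
    n_driver_genes: int = 40
    n_driver_modules: int = 8       # drivers (and response signal) live here
    network_avg_degree: float = 8.0
    within_module_frac: float = 0.8
    n_fingerprint_bits: int = 128
    fingerprint_density: float = 0.1
    mutation_rate_range: tuple[float, float] = (0.05, 0.4)
    expression_noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.7, 1.3)
    w_activity: float = 1.0
    w_mutation: float = 0.7
    w_drug: float = 1.0
    w_interaction: float = 0.3
    noise_sd: float | None = None   # None: 0.5 x sd of the noiseless response
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_cells, self.n_drugs, self.n_pathways,
                  self.n_driver_genes, self.n_driver_modules,
                  self.n_fingerprint_bits)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_pathways > self.n_genes:
            raise ValueError("more pathways than genes")
        if self.n_driver_modules > self.n_pathways:
            raise ValueError("driver modules exceed module count")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    network: Network
    modules: np.ndarray                 # module index per network node
    driver_genes: list[str]
    collection: dict[str, set[str]]     # planted + decoy gene sets
    planted_pathways: list[str]
    expression: pd.DataFrame            # gene x cell
    mutations: pd.DataFrame             # driver gene x cell (binary)
    fingerprints: pd.DataFrame          # bit x drug (binary)
    pairs: pd.DataFrame                 # cell_id, drug_id, ln_ic50, source
    edge_records: list[tuple[str, str, str]]
    ground_truth: dict = field(default_factory=dict)


def _module_sizes(
    n_genes: int, n_modules: int, size_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = size_range
    draw = rng.integers(lo, hi + 1, size=n_modules).astype(float)
    sizes = np.maximum(2, np.round(draw * n_genes / draw.sum()).astype(int))
    # fix rounding drift so sizes partition the genes exactly
    while sizes.sum() > n_genes:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_genes:
        sizes[np.argmin(sizes)] += 1
    return sizes


def simulate_network(
    n_genes: int,
    avg_degree: float,
    n_modules: int,
    seed: int | np.random.Generator = 0,
    within_module_frac: float = 0.8,
    size_range: tuple[int, int] | None = None,
) -> tuple[Network, np.ndarray]:
    """Stochastic-block-style gene network, connected by construction.

    Roughly ``within_module_frac`` of the edges fall inside modules.  After
    edge sampling, any disconnected component is joined to the first component
    by one extra edge (spanning-tree augmentation), so the result is always
    connected, symmetric, and zero-diagonal.
    """
    if n_modules < 1 or n_genes < n_modules:
        raise ValueError("need n_genes >= n_modules >= 1")
    if not (0 < avg_degree < n_genes):
        raise ValueError("average degree must be in (0, n_genes)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if size_range is None:
        base = n_genes // n_modules
        size_range = (max(2, base - 2), base + 2)
    sizes = _module_sizes(n_genes, n_modules, size_range, rng)
    modules = np.repeat(np.arange(n_modules), sizes)
    width = len(str(n_genes))
    node_ids = [f"G{i:0{width}d}" for i in range(n_genes)]

    n_edges = int(round(n_genes * avg_degree / 2))
    n_within = int(round(within_module_frac * n_edges))
    adj = np.zeros((n_genes, n_genes))
    starts = np.concatenate([[0], np.cumsum(sizes)])

    def add_edge(i: int, j: int) -> bool:
        if i == j or adj[i, j]:
            return False
        adj[i, j] = adj[j, i] = 1.0
        return True

    added = 0
    attempts = 0
    while added < n_within and attempts < 50 * n_within:
        m = int(rng.integers(n_modules))
        lo, hi = starts[m], starts[m + 1]
        i, j = rng.integers(lo, hi, size=2)
        added += add_edge(int(i), int(j))
        attempts += 1
    while added < n_edges and attempts < 100 * n_edges:
        i, j = rng.integers(n_genes, size=2)
        added += add_edge(int(i), int(j))
        attempts += 1

    # connect stray components to the component of node 0
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_comp > 1:
        anchor_label = labels[0]
        anchors = np.nonzero(labels == anchor_label)[0]
        for comp in range(n_comp):
            if comp == anchor_label:
                continue
            members = np.nonzero(labels == comp)[0]
            i = int(rng.choice(members))
            j = int(rng.choice(anchors))
            add_edge(i, j)
    return Network(node_ids, adj), modules


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Generate a full cohort from the spec; bitwise-identical given the seed."""
    streams = dict(zip(_STREAMS, np.random.SeedSequence(spec.seed).spawn(len(_STREAMS))))
    rngs = {name: np.random.default_rng(s) for name, s in streams.items()}

    net, modules = simulate_network(
        spec.n_genes, spec.network_avg_degree, spec.n_pathways,
        rngs["network"], spec.within_module_frac, spec.pathway_size,
    )
    genes = np.array(net.node_ids, dtype=object)
    cells = [f"CELL{i:03d}" for i in range(spec.n_cells)]
    drugs = [f"DRUG{i:02d}" for i in range(spec.n_drugs)]

    # pathways = modules; decoys = random gene sets of comparable size
    collection: dict[str, set[str]] = {}
    planted = []
    for k in range(spec.n_pathways):
        name = f"PW{k:02d}_MODULE"
        collection[name] = set(genes[modules == k].tolist())
        planted.append(name)
    rng_net = rngs["network"]
    decoy_size = max(5, spec.n_genes // spec.n_pathways)
    for k in range(spec.n_decoy_pathways):
        members = rng_net.choice(spec.n_genes, size=decoy_size, replace=False)
        collection[f"DECOY{k:02d}"] = set(genes[members].tolist())

    # drivers concentrated in the first n_driver_modules modules
    rng_mut = rngs["mutation"]
    driver_modules = np.arange(spec.n_driver_modules)
    per_module = np.array_split(np.arange(spec.n_driver_genes), spec.n_driver_modules)
    driver_idx: list[int] = []
    for m, chunk in zip(driver_modules, per_module):
        pool = np.nonzero(modules == m)[0]
        take = min(len(chunk), len(pool))
        driver_idx.extend(rng_mut.choice(pool, size=take, replace=False).tolist())
    driver_idx = sorted(driver_idx)
    driver_genes = [str(g) for g in genes[driver_idx]]

    # expression: per-cell module activities with gene loadings + noise
    rng_expr = rngs["expression"]
    activity = rng_expr.standard_normal((spec.n_pathways, spec.n_cells))
    loadings = rng_expr.uniform(*spec.loading_range, size=spec.n_genes)
    expr = (
        loadings[:, None] * activity[modules, :]
        + spec.expression_noise_sd * rng_expr.standard_normal((spec.n_genes, spec.n_cells))
    )
    expression = pd.DataFrame(expr, index=genes, columns=cells)

    # mutations: Bernoulli per driver gene; latent = weighted driver burden
    rates = rng_mut.uniform(*spec.mutation_rate_range, size=len(driver_genes))
    mut = (rng_mut.random((len(driver_genes), spec.n_cells)) < rates[:, None]).astype(np.int8)
    mut_weights = rng_mut.standard_normal(len(driver_genes))
    mut_latent = _standardize(mut_weights @ mut)
    mutations = pd.DataFrame(mut, index=driver_genes, columns=cells)

    # fingerprints: Bernoulli bits; latent = weighted bit sum
    rng_drug = rngs["drugs"]
    fp = (rng_drug.random((spec.n_fingerprint_bits, spec.n_drugs))
          < spec.fingerprint_density).astype(np.int8)
    fp_weights = rng_drug.standard_normal(spec.n_fingerprint_bits)
    drug_latent = _standardize(fp_weights @ fp)
    fingerprints = pd.DataFrame(fp, index=pd.RangeIndex(spec.n_fingerprint_bits, name="bit"),
                                columns=drugs)

    # response: linear in driver-module activity, mutation and drug latents
    rng_resp = rngs["response"]
    module_weights = rng_resp.uniform(0.5, 1.5, size=spec.n_driver_modules)
    act_latent = _standardize(module_weights @ activity[driver_modules, :])
    noiseless = (
        spec.w_activity * act_latent[:, None]
        + spec.w_mutation * mut_latent[:, None]
        + spec.w_drug * drug_latent[None, :]
        + spec.w_interaction * np.outer(mut_latent, drug_latent)
    )
    noise_sd = spec.noise_sd if spec.noise_sd is not None else 0.5 * noiseless.std()
    response = noiseless + noise_sd * rng_resp.standard_normal(noiseless.shape)

    cell_col = np.repeat(cells, spec.n_drugs)
    drug_col = np.tile(drugs, spec.n_cells)
    pairs = pd.DataFrame({
        "cell_id": cell_col,
        "drug_id": drug_col,
        "ln_ic50": response.ravel(),
        "source": "SCREEN2",
    })

    # edge list: every true edge under two sources, plus single-source decoys
    edge_records = []
    true_edges = net.to_edge_records()
    for a, b, _ in true_edges:
        edge_records.append((a, b, "src_alpha"))
        edge_records.append((a, b, "src_beta"))
    existing = {(a, b) for a, b, _ in true_edges}
    n_decoy_edges = max(1, len(true_edges) // 10)
    added = 0
    while added < n_decoy_edges:
        i, j = rng_net.integers(spec.n_genes, size=2)
        if i == j:
            continue
        a, b = (str(genes[min(i, j)]), str(genes[max(i, j)]))
        if (a, b) in existing:
            continue
        existing.add((a, b))
        edge_records.append((a, b, "src_gamma"))
        added += 1

    ground_truth = {
        "modules": modules.tolist(),
        "driver_modules": driver_modules.tolist(),
        "activity": activity.tolist(),
        "loadings": loadings.tolist(),
        "mutation_weights": mut_weights.tolist(),
        "mutation_latent": mut_latent.tolist(),
        "fingerprint_weights": fp_weights.tolist(),
        "drug_latent": drug_latent.tolist(),
        "module_weights": module_weights.tolist(),
        "activity_latent": act_latent.tolist(),
        "noiseless": noiseless.tolist(),
        "noise_sd": float(noise_sd),
        "weights": {
            "w_activity": spec.w_activity,
            "w_mutation": spec.w_mutation,
            "w_drug": spec.w_drug,
            "w_interaction": spec.w_interaction,
        },
    }
    return SyntheticCohort(
        spec, net, modules, driver_genes, collection, planted,
        expression, mutations, fingerprints, pairs, edge_records, ground_truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as plain-text files plus a checksum manifest.

    Files: ppi_edges.tsv, drivers.txt, gene_sets.gmt, expression.tsv,
    mutations.tsv, fingerprints.tsv, pairs.tsv, ground_truth.json,
    manifest.json.  ``read_fixture`` round-trips the cohort exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    edges = pd.DataFrame(cohort.edge_records, columns=["geneA", "geneB", "source"])
    edges.to_csv(directory / "ppi_edges.tsv", sep="\t", index=False)
    (directory / "drivers.txt").write_text("\n".join(cohort.driver_genes) + "\n")
    write_gmt(directory / "gene_sets.gmt", cohort.collection)
    # %.17g guarantees bitwise float64 round-trip through text
    cohort.expression.to_csv(directory / "expression.tsv", sep="\t",
                             index_label="gene", float_format="%.17g")
    cohort.mutations.to_csv(directory / "mutations.tsv", sep="\t", index_label="gene")
    cohort.fingerprints.to_csv(directory / "fingerprints.tsv", sep="\t", index_label="bit")
    cohort.pairs.to_csv(directory / "pairs.tsv", sep="\t", index=False,
                        float_format="%.17g")
    (directory / "ground_truth.json").write_text(
        json.dumps({"planted_pathways": cohort.planted_pathways, **cohort.ground_truth})
    )

    files = sorted(p.name for p in directory.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "spec": asdict(cohort.spec),
        "files": {name: _sha256(directory / name) for name in files},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Reload a written fixture into an equivalent cohort object."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_dict = dict(manifest["spec"])
    for key in ("pathway_size", "mutation_rate_range", "loading_range"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = CohortSpec(**spec_dict)

    edges = pd.read_csv(directory / "ppi_edges.tsv", sep="\t", dtype=str)
    edge_records = list(edges.itertuples(index=False, name=None))
    network = filter_edges(edge_records, min_sources=2)
    drivers = [
        line.strip() for line in (directory / "drivers.txt").read_text().splitlines()
        if line.strip()
    ]
    collection = {k: set(v) for k, v in read_gmt(directory / "gene_sets.gmt").items()}
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
    expression.index.name = None  # round-trip: in-memory frames carry no index label
    mutations = pd.read_csv(directory / "mutations.tsv", sep="\t", index_col=0)
    mutations.index.name = None
    fingerprints = pd.read_csv(directory / "fingerprints.tsv", sep="\t", index_col=0)
    pairs = pd.read_csv(directory / "pairs.tsv", sep="\t",
                        dtype={"cell_id": str, "drug_id": str, "source": str},
                        float_precision="round_trip")
    gt = json.loads((directory / "ground_truth.json").read_text())
    planted = gt.pop("planted_pathways")
    modules = np.array(gt["modules"], dtype=int)
    return SyntheticCohort(
        spec, network, modules, drivers, collection, planted,
        expression, mutations, fingerprints, pairs, edge_records, gt,
    )
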