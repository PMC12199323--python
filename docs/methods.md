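# Methods

This note documents the models implemented in `driversig`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical decisions that affect results.

## Network propagation

The PPI network is built from an edge list of (geneA, geneB, source) records:
an undirected edge is kept when the unordered pair is observed under at least
`min_sources = 2` *distinct* source tags; self-pairs and duplicate
observations are discarded. Gene identifiers are matched by exact string
equality after whitespace stripping — symbol/alias mapping is an
input-preparation concern, not handled here. The largest connected component
is extracted (ties between equal-size components go to the one containing the
lexicographically smallest identifier, for determinism), guaranteeing every
node has degree ≥ 1.

Random walk with restart iterates `c(t+1) = (1−β)·T·c(t) + β·c0` with
`T[i,j] = P[i,j]/deg(j)` (column-stochastic: each column j distributes the
mass leaving gene j), `c0` uniform over the mapped seed genes, and restart
probability `β = 0.9` — a high restart keeps probability mass near the
drivers, probing their immediate network neighbourhood rather than global
diffusion. Convergence is declared when the max-norm difference between
successive iterates falls below `tol = 1e−10`; the iteration cap
(`max_iter = 10 000`) is a safety bound — at β = 0.9 the map contracts with
factor 0.1 per step, so convergence takes ~11 iterations. Because T is
column-stochastic and the update is a convex combination, Σc = 1 is preserved
at every step; the test suite verifies the fixed point against the
closed-form solve `β(I − (1−β)T)⁻¹c0` to < 1e−8.

## Enrichment

`enrichment_score` is the weighted Kolmogorov–Smirnov statistic: walking down
the ranked list, hits advance the running sum by |w|^exponent (normalized
over the set's hits) and misses retreat by 1/(N − |S|); the ES is the signed
maximum deviation, and the leading edge collects the set members at or before
the peak (positive ES) or at or after the trough (negative ES). Ties in the
ranking are broken by input order under a stable sort; constant rankings are
rejected rather than silently ordered.

Significance uses a gene-label permutation null — `n_perm = 1000` random
gene sets of matched size drawn from the ranked universe — because phenotype
permutation does not exist for a preranked list. The empirical p-value is
one-sided within the sign of the observed ES (for ES > 0, the fraction of
non-negative null ES values at least as large, with the +1 correction), which
makes p approximately uniform under the null; a two-sided pool would compress
p into [0, 0.5]. FDR is Benjamini–Hochberg over the collection — simpler and
monotone compared to the NES-based procedure of the original GSEA tooling.
Signature selection keeps pathways with ES > 0 and FDR < 0.2 (both strict),
ordered by ascending FDR then descending ES.

**Weighting exponent.** `gsea` defaults to exponent 1 (the classic weighted
statistic). The characterization pipeline, however, calls it with
**exponent 0.25**: the propagation vector is a probability distribution whose
mass concentrates on the seed genes (>90% at β = 0.9), and with exponent 1
essentially every gene set — real or random — attains ES ≈ 0.9 from its
single highest-weighted member, destroying the statistic's power. Damping to
the quarter power (the same tempering ssGSEA applies to ranks) restores
discrimination; on the synthetic cohort it recovers exactly the planted
driver modules and rejects all decoys.

`ssgsea_sample` is the per-sample rank statistic: genes are ordered by
descending expression within the sample, the gene at 0-based position i
carries rank value N − i, hits are weighted by rank^α (α = 0.25) normalized
over the set, misses uniformly, and the activity is the sum over all
positions of P_hit − P_miss. It depends only on within-sample ranks, so it is
exactly invariant under strictly monotone transforms of a sample. Raw scores
scale with N (≈ ±N/2); `activity_matrix` can min–max normalize the matrix to
[0, 1], and the pipeline enables this by default so the expression embedding
lives on the same scale as the autoencoder bottlenecks — without it the
activity block is ~10² times larger than every other regressor input and
joint training degrades badly. Constant expression columns are rejected
(ranks undefined up to ties), as are sets covering the whole gene universe.

## Feature preparation

Mutation binarization marks (gene, sample) = 1 when at least one variant
record carries a protein-altering class (missense, nonsense, frameshift
ins/del, splice site, in-frame ins/del, nonstop, translation start site —
case-insensitive and configurable); known silent/UTR/intron classes are
quietly non-qualifying, unknown classes warn. Expression is
log₂(TPM + 1) by default (base and pseudocount configurable — the convention,
not a derived quantity). Drugs are folded Morgan fingerprints, 1024 bits at
radius 2 (ECFP4-equivalent). Pair tables deduplicate (cell, drug) by a
configurable source-precedence list (newer screen beats older by default);
conflicting duplicates within one source are an error, not a silent pick.
Cancer-type cohorts smaller than 10 cell lines can be dropped with
`filter_small_groups`.

## Neural model

Autoencoders: encoder input→h1→h2→bottleneck, each dense layer followed by
batch normalization and ReLU; the decoder mirrors the widths and ends in a
sigmoid so reconstructions lie in (0, 1). The regressor has two hidden layers
exactly as wide as its input (signature size + both bottlenecks) and a single
linear output neuron, leaving LN IC50 unbounded. Reference widths are
(300, 100, 30) for 534-gene mutation and 1024-bit drug inputs; for other
input sizes `default_ae_spec` scales these proportionally (0.8/0.4/0.2 of the
input, capped at the reference values).

The unified loss is MSE(S, S′) + λ_C·BCE(R_C, R_C′) + λ_D·BCE(R_D, R_D′)
with λ = 1; BCE is averaged over all elements, so at p ≡ 0.5 each term equals
ln 2. Training uses Adam (lr 1e−3, batch 1024 by default), shuffled
mini-batches, up to 100 epochs, and early stopping with patience 10 on the
validation **unified** loss (a `monitor="prediction"` option watches
validation MSE instead; on the synthetic cohort the two behave equivalently).
The best-validation state is restored on exit, so the returned model is never
worse than any earlier epoch on the monitored quantity. Training gradients
for the decoders use the numerically exact BCE-with-logits form (the sigmoid
is applied outside the layer stack).

Everything is float64 with Glorot-uniform initialization from named
substreams of a single seed; batch-normalization inference uses frozen
running averages (momentum 0.1, unbiased variance). Identical configuration
and seed give bitwise-identical training histories on one thread, and
checkpoints (a single `.npz` of weights, running statistics, specs, and
history) reload to bitwise-identical predictions. The engine is a small
hand-written dense-network stack on numpy; its backward passes are verified
against central finite differences in the test suite.

Width pretraining (`pretrain_autoencoder`) grid-searches
h1 ∈ {300, 200, 100} × h2 ∈ {100, 50, 30} × b ∈ {30, 20, 10} for 50 epochs
each and selects the lowest held-out reconstruction BCE (ties → fewer
parameters). Hyperparameter search (`grid_search`) covers
lr ∈ {1e−2, 1e−3, 1e−4} × batch ∈ {256, 512, 1024} at 50 epochs and ranks by
ascending test RMSE with descending-PCC tie-break. End-to-end training starts
from fresh weights by default; carrying pretrained weights forward is
available but in our experiments did not improve generalization.

## Evaluation

Partition fractions (0.8, 0.1, 0.1) are allocated by largest remainder, so
split sizes are deterministic. `mix` partitions pairs; `cell`/`drug`
partition the entities and pairs follow; `both` partitions cells and drugs
independently and keeps a pair only when both its entities land in the same
partition, discarding (and counting) cross-partition pairs — test pairs under
`both` therefore have an unseen cell *and* an unseen drug.

The quartile rule takes τ as the 25th percentile of the *observed* LN IC50
(linear interpolation between order statistics); pairs with value ≤ τ are
"sensitive" (the positive class, consistent with lower IC50 = more
sensitive). F1 applies the same τ to predictions; AUROC ranks by the negated
prediction so that a higher score means more sensitive. Per-entity metrics
skip entities with fewer than 3 pairs or constant observations (counted, not
silently dropped); PCC for a constant target is reported as NaN, never as 0.
Monte Carlo CV re-splits 8:1:1 with seeds spawned deterministically from a
master seed and retrains from scratch each iteration.

## Interpretation

Integrated Gradients is computed with respect to the regressor's input layer
— pathway activities and the two bottleneck embeddings — so attributions are
directly per-pathway and per-embedding-dimension; they are deliberately not
propagated back through the encoders. The path integral from the all-zeros
baseline uses a **midpoint** Riemann sum with 50 steps by default: for the
piecewise-linear ReLU regressor the one-sided rules converge only at O(1/m)
and miss the completeness axiom by several percent at 200 steps, while the
midpoint rule is exact between kinks (verified < 1% at 200 steps on trained
models, and exact for affine models at any step count). The IG score is the
per-feature mean attribution over samples: negative values push predicted
LN IC50 down, i.e. mark sensitivity-increasing features; rankings use the
absolute score while signed scores are reported.

Embedding annotation correlates each mutation-embedding dimension with every
gene's expression across shared samples (constant genes excluded, constant
dimensions skipped and reported), ranks genes by correlation, and runs
preranked GSEA per dimension; pathways with FDR < 0.01 (configurable — a
looser 0.05 is also defensible) annotate the dimension with the sign of
their ES. Note the empirical-p floor: with n_perm permutations and m sets the
smallest attainable BH-adjusted FDR is about 2m/n_perm, so small collections
need n_perm well above 1000 to resolve FDR < 0.01.

Cells are grouped sensitive/insensitive by the first quartile of their mean
LN IC50 across drugs (≤ τ sensitive), the same percentile convention as the
classifier.

## Synthetic cohort

The generator produces a self-contained screen with the statistical structure
the pipeline assumes, with all randomness drawn from named substreams
(network, expression, mutation, drugs, response) of one master seed. Defaults
— the reference study conditions — are 500 genes, 200 cell lines, 50 drugs,
20 network modules of 20–30 genes, 20 random decoy gene sets, 40 driver genes
spread over the first 8 modules, average degree 8 with 80% of edges
within-module, 128 fingerprint bits at density 0.1, expression noise sd 0.3
around loadings U(0.7, 1.3), and mutation rates U(0.05, 0.4).

Pathways coincide with network modules so that propagation from the planted
drivers genuinely enriches the planted pathways, making the signature
selection testable end to end; decoys give it true negatives. The response is
linear in three standardized latents plus a small interaction:

    LN IC50(c, d) = 1.0·activity(c) + 0.7·mutation(c) + 1.0·drug(d)
                    + 0.3·mutation(c)·drug(d) + ε,

where activity(c) is a weighted sum of the driver-module activities,
mutation(c) a weighted driver-burden, drug(d) a weighted fingerprint-bit sum,
and ε Gaussian with sd = 0.5 × the noiseless response sd. That noise level
caps attainable R² at 0.8 (PCC ≈ 0.89); an OLS fit on the true latents
reaches held-out R² ≈ 0.8, and the full pipeline reaches test PCC ≈ 0.87
under the mix split at these conditions.

What the cohort does *not* emulate: realistic TPM distributions (expression
is Gaussian around module activity), mutational signatures or co-occurrence,
chemically valid molecules (fingerprint bits are abstract and independent),
dose–response curve fitting, or batch effects. Passing tests therefore
demonstrate that the pipeline recovers planted linear structure through its
rank statistics and embeddings — not that it matches published performance on
real screens. Two scale-dependent caveats matter when reading results at the
default size: (i) under the doubly-unseen split the test partition is only
100 pairs with 5 unseen drugs, so test PCC has large seed-to-seed variance
(even a ridge oracle on the same features spans ≈ 0.4–0.6 across seeds); and
(ii) real fingerprints have correlated substructure that helps unseen-drug
generalization, which independent Bernoulli bits do not provide.

## Known limitations

- The GSEA FDR is BH over empirical permutation p-values, not the NES-based
  FDR of the original GSEA software; NES and multi-level p-refinement are out
  of scope.
- The network is unweighted and undirected; no alias resolution.
- Training is single-threaded CPU; the bitwise-reproducibility guarantee
  assumes one thread.
- The quartile threshold convention (lowest-LN IC50 quartile = sensitive) is
  configurable but the package default treats sensitivity as the positive
  class everywhere.
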