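# Methods

## The prioritization model

`lncwalk` scores candidate lncRNAs for a disease phenotype by a random walk
with restart (RWR) on a heterogeneous composite network with three node
layers — genes, disease phenotypes, lncRNAs — and six weighted association
blocks: W_G (gene–gene, e.g. protein interaction), W_P (phenotype–phenotype
similarity), W_L (lncRNA–lncRNA co-expression) and the cross-layer blocks
W_GP, W_GL, W_PL. Edge weights follow the evidence of each association:
experimentally validated edges carry weight 1.0, computationally predicted
edges carry their correlation (or similarity) value in (0, 1). The model
assumes guilt by association: lncRNAs functionally related to a disease's
known genes and lncRNAs, directly or through network proximity, are more
likely to be disease-relevant.

### Transition matrix

The transition matrix M is assembled per row. For a node in layer A with
potential bridge layers B and C, each bridge block in which the node has at
least one edge receives exactly the jump probability of that layer pair —
x (gene↔phenotype), y (gene↔lncRNA), z (phenotype↔lncRNA) — distributed
proportionally to edge weights; the intra-layer block, if the node has
intra-layer edges, receives the remaining mass (1, 1−jB, 1−jC or 1−jB−jC
depending on which bridges are present). Two degenerate cases need a rule:

- A node with bridge edges but no intra-layer edges would be left with total
  row mass below 1 (for example a phenotype connected only to genes and
  lncRNAs has mass x + z). We rescale such rows to sum exactly 1, preserving
  the proportional structure while keeping M a proper Markov kernel. The
  unrescaled variant is available via
  `build_transition(..., rescale_substochastic=False)` for sensitivity
  checks; it changes absolute scores but rarely rankings.
- Edge-free (dangling) nodes keep all-zero rows. No teleportation self-loop
  is added: walker mass that enters a dangling node is recovered only through
  the restart term, so with dangling nodes present the stationary scores sum
  to slightly less than 1. Rankings are unaffected; dangling candidates score
  0 and rank last. A `--normalize` flag on the CLI divides reported scores by
  their sum.

The pairwise constraints x+y ≤ 1, x+z ≤ 1, y+z ≤ 1 guarantee nonnegative
intra-layer mass in the worst case of two active bridges.

### Seeds and propagation

The initial vector p⁰ mixes the query phenotype (S^P), its known disease
genes (S^G) and its known disease lncRNAs (S^L). Seeds within a layer share
that layer's probability uniformly; the layers are then weighted α (genes),
β (phenotypes) and 1−α−β (lncRNAs). When a layer has no seeds — common in
practice, since many diseases have no known lncRNAs — its weight is
redistributed proportionally over the seeded layers' weights (uniformly if
those are all zero). This keeps zero-known-lncRNA queries well defined
without changing the behaviour of fully seeded queries. Seed ids missing
from the network are dropped with a warning; only an entirely unmappable
seed set is fatal.

Propagation iterates p^{t+1} = (1−δ) Mᵀ p^t + δ p⁰ until the L1 norm of the
difference between successive iterates falls below the tolerance (default
10⁻¹⁰, typically 20–40 iterations at δ = 0.7; a hard cap of 10 000
iterations raises an error rather than returning an unconverged vector).
Convergence is measured on successive iterates: the mapping is a
(1−δ)-contraction in L1, so the criterion terminates for every δ in (0, 1].
A dense closed-form solver, p = δ (I − (1−δ) Mᵀ)⁻¹ p⁰, serves as an exact
oracle for networks up to 2000 nodes and is cross-checked against the
iterative path in the tests. Candidates are ranked by stationary score,
descending, with lexicographic id as the deterministic tie-break.

### Defaults

δ = 0.7, x = y = z = 1/3, α = β = 1/3 (so all three layers contribute
equally to both the walk and the seed vector). These are the standard
operating point; the `parameter_sweep` facility reruns cross-validation over
any grid on {δ, x, y, z, α, β} and in our benchmarks the pooled AUC moves
by only a few points across reasonable grids, consistent with RWR's usual
insensitivity to the restart probability.

## Network construction

Edge lists are consumed as TSV (source, target, weight, evidence); loading
validates weights in (0, 1], rejects self-loops and reports all offending
line numbers at once. When the same node pair arrives from several sources,
experimental evidence (weight 1.0) takes precedence over predicted, and
among equal-evidence duplicates the maximum weight is kept — merging is
idempotent. Intra-layer pairs appearing in both orientations keep the
maximum weight. Node ids must be unique across layers; callers must
disambiguate symbols used for both a gene and a lncRNA.

Co-expression edges are computed from an entity × sample expression matrix
(FPKM-like) by Pearson correlation, requiring at least 3 samples;
zero-variance profiles are skipped with a warning. Two policies are offered:
`absolute` (keep |r| ≥ threshold at weight |r|, the default) and
`signed_positive` (keep r ≥ threshold at weight r). The default threshold is
0.6; the right cutoff is data-dependent, so it is a parameter, and whether
anti-correlated pairs should count as functional association is left to the
policy choice. Phenotype similarity networks are sparsified by keeping each
phenotype's top-k most similar neighbours (default k = 5), symmetrized by
union — an edge survives if either endpoint ranks the other in its top k —
with ties at the k-th weight broken lexicographically.

Networks serialize as a directory of six canonical TSVs plus a JSON manifest
carrying the full node registries (so isolated candidate lncRNAs survive a
round trip) and per-file checksums.

## Evaluation

Leave-one-out cross-validation iterates over known phenotype–lncRNA
associations of phenotypes with at least `min_known_lncrnas` (default 2)
known lncRNAs. Each fold removes the held-out link from W_PL, seeds with the
phenotype, its remaining known lncRNAs and all its known genes, propagates,
and records the held-out lncRNA's rank among all non-seed lncRNAs. The
scenario `no_known_lncrnas` instead removes all of the phenotype's known
lncRNA links and seeds only the phenotype and its genes, emulating diseases
with no lncRNA annotations; `layer_ablation` restricts the walk to a layer
subset (e.g. phenotype+lncRNA only, or lncRNA only), reproducing the designs
of simpler two-layer and single-layer propagation baselines inside the same
engine.

Folds have different candidate counts, so pooling is done on a common rank
axis: each fold's positive sits at percentile (rank−1)/(n−1) and its n−1
negatives occupy the remaining rank percentiles. The pooled empirical step
ROC over these positions is integrated by the trapezoid rule; with the
diagonal tie segments this equals the Mann–Whitney statistic (half credit
for ties), which the tests verify against a brute-force pairwise count.
Per-fold AUC is 1 − percentile. Top-k recall counts folds with rank ≤ k (or
rank ≤ ceil(f·n) for a fractional cutoff f, evaluated per fold). Per-class
AUCs are computed from an explicit phenotype → disease-class table when one
is supplied.

The landscape facility scores every phenotype (seeded with its full known
gene/lncRNA sets, nothing held out) against every lncRNA in one transition
model, producing a phenotype × lncRNA score matrix; hotspot counting reports,
for each lncRNA and each cutoff k, the number of phenotypes where it ranks in
the top k — counts are monotone in k by construction.

## The synthetic benchmark

Real composite networks are assembled from curated interaction, similarity
and co-expression resources that cannot be bundled; the generator instead
emulates their statistical shape with a layered stochastic block model. Each
planted disease owns one phenotype, a gene module and a lncRNA module.
Intra-module gene–gene and lncRNA–lncRNA edges appear with probability
`p_in` (default 0.6) and carry predicted weights drawn uniformly from
`predicted_weight_range` (default (0.5, 0.9), a realistic co-expression
band); background intra-layer edges appear with probability `p_out` (0.02).
Gene–lncRNA bridges are dense inside a module (`q_bridge` = 0.5) and sparse
elsewhere (`bg_bridge` = 0.01). A subset of each module (3 genes and 3
lncRNAs per disease by default) is designated "known" and wired to the
phenotype with experimental weight-1 edges — these are the associations
cross-validation holds out. Optional `shared_module_pairs` make two diseases
reuse one module and add a phenotype–phenotype edge, planting the similar-
disease structure that the phenotype layer is meant to exploit. The default
layer sizes (50 genes, 10 phenotypes, 40 lncRNAs, 5 diseases) keep the full
cross-validation suite under a few seconds while leaving most lncRNAs
outside any module as realistic negatives.

The expression generator gives module members a shared lognormal latent
profile plus independent noise (`expression_noise`, default 0.3) over
`n_samples` samples (default 50), so within-module Pearson correlations are
high (exactly 1 at zero noise) and background pairs are uncorrelated.

What the benchmark does *not* emulate: the heavy-tailed degree distributions
of real interactomes, ascertainment bias in curated disease annotations,
correlated noise between co-expression and interaction evidence, and id
mapping issues. Passing the planted-recovery tests therefore demonstrates
that the engine propagates and ranks correctly on modular guilt-by-
association structure — not that any particular AUC will be attained on a
specific real data assembly.

All generator randomness flows through one `numpy.random.default_rng`
instance seeded by `rng_seed`; a configuration maps deterministically and
bitwise-reproducibly to a network.

## Numerical and design notes

- Blocks are stored dense (the intended scale is 10²–10⁴ nodes); the
  transition matrix is CSR sparse and propagation is a sparse mat-vec.
- Ties anywhere in ranking resolve lexicographically by node id, making every
  derived quantity (percentiles, ROC, hotspot counts) deterministic.
- Stationary scores are not renormalized before ranking (ranking-invariant);
  reporting can normalize on request.
- Fold percentile uses (rank−1)/(n−1), 0 for a single-candidate fold.
- The CLI (`simulate`, `rank`, `loocv`, `landscape`, `sweep`) is a thin layer
  over the library; all logic is importable and unit-tested directly.

## Limitations

- Multi-phenotype joint queries are not supported; run one walk per
  phenotype.
- Raw-data processing (read alignment, text-mining similarity, database
  extraction) is out of scope: the package consumes pre-extracted edge lists
  and expression tables.
- The closed-form oracle is dense and guarded to ≤ 2000 nodes; beyond that
  only the iterative path is available.
- Evaluation metrics assume each fold's negatives are exchangeable
  non-associated lncRNAs; contaminated negatives (true but unannotated
  associations) bias the pooled AUC downward.
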