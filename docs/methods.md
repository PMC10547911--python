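# Methods

## Problem and model

Given a cells × genes count matrix, the package seeks a gene subset on
which K-means clustering of the cells is simultaneously compact/separated
(high silhouette) and small (few genes), then clusters cells on that
subset. Feature selection is *wrapper-style*: each candidate subset is
evaluated by actually running the clusterer, so the objective sees exactly
what the final analysis will see.

### Preprocessing

1. **Zero-gene filter** — genes with zero total count are removed; an
   all-zero matrix is an error rather than an empty result.
2. **Library-size normalization** — each cell's counts are scaled to a
   common target (default: median per-cell total), then transformed by
   log2(x + 1). The linear (pre-log) intermediate is exactly invariant to
   multiplying all counts by a common factor; the log transform is not,
   which is the usual behavior of this recipe.
3. **HVG screen** — genes are ranked by dispersion (variance/mean of
   log-expression), z-scored within 20 equal-width mean-expression bins so
   that lowly and highly expressed genes compete fairly, and the top D
   (default 2000) are kept in their original order. Constant genes are
   assigned a −inf score: a gene with no variation can never be "variable",
   and this guarantees deterministic exclusion regardless of binning
   pathologies at small gene counts. Any deterministic variability ranking
   would serve; the binned-dispersion flavor is the common default in
   single-cell toolchains.

### Search space and encoding

A candidate solution is a vector of D angles θ ∈ [θL, θU]. Each angle
encodes a quantum bit cos θ|0⟩ + sin θ|1⟩ whose amplitudes squared sum to
one by construction; the bit (gene included or not) is the measurement
bit = 1 iff |cos θ|² ≤ |sin θ|². Bounds are θL = 0, θU = π/2 so both
amplitudes are valid probabilities and the inclusion threshold sits at the
midpoint π/4; uniform initialization therefore yields masks with ~50% of
genes selected. Numerically, cos²(π/4) and sin²(π/4) differ by one ulp, so
the inclusion test uses a 1e−12 tolerance to keep the boundary angle
inclusive.

### Fitness

    Fitness(S) = w · SC(ŷ(S)) + (1 − w) · (1 − |S|/D),   w = 0.9 default

- K-means: 5 restarts, 100 Lloyd iterations, greedy k-means++ seeding,
  seeded from the caller's random stream (deterministic given the seed).
- Silhouette: Euclidean, all cells, singleton clusters contribute 0. If
  the clustering collapses to a single non-empty cluster the silhouette is
  set to −1 (worst) so the mask is penalized rather than crashing the
  search. A subsampled silhouette is unnecessary at the problem sizes this
  package targets and is deliberately not implemented behind a default.
- An empty mask is inadmissible: it receives a −inf sentinel, can never
  become the best-ever solution, and the search is guaranteed to return a
  non-empty mask.
- Admissible values lie in [−w, w + (1−w)(1 − 1/D)].

### Population dynamics

Population 50: after every evaluation round squirrels are ranked by
fitness (ties: fewer selected genes, then lower index) into 1 hickory,
3 acorn, 46 normal trees. Per iteration:

1. Acorn squirrels glide toward the hickory; each normal squirrel glides
   either toward a uniformly chosen acorn or directly toward the hickory
   (independent fair coin per squirrel per iteration — the split ratio is
   a free design choice here). Moves are *synchronous*: all targets are
   frozen at the iteration start.
2. A glide is θ′ = θ + dg·Gc·(θ_target − θ) with one scalar glide distance
   dg ~ U[0.3, 0.7] per move shared across dimensions and gliding constant
   Gc = 1.9; with predator probability Pdp = 0.1 the move is replaced by a
   fresh uniform position in [θL, θU]^D. Results are clipped into bounds.
3. Seasonal monitoring: for each acorn, Sc = Σk (θ_acorn,k − θ_hickory,k)²
   (no square root — following the printed form of the recurrence this
   implements). If any acorn satisfies Sc < Smin(t) = 10⁻⁶/365^(t/(tm/2.5)),
   all normal-tree squirrels are relocated to θL + Lévy·(θU − θL) with
   Mantegna-algorithm Lévy steps (stability index 1.5), clipped to bounds.
   Dividing by the 365-power makes Smin strictly decreasing, so relocation
   becomes rarer as the search exploits; the alternative reading
   (multiplying) would make the threshold grow without bound and relocate
   constantly, which contradicts the stated purpose of the schedule.
4. Moved squirrels are re-binarized and re-evaluated; unmoved squirrels
   keep their cached fitness (so a mask keeps the K-means draw it was
   scored with). Roles are re-assigned once per iteration.

The best-ever squirrel is stored outside the population (elitism): the
convergence trace of best fitness is non-decreasing by construction, and
relocation can never destroy the incumbent.

### Final clustering and K

With K supplied, the final labels are K-means on the selected genes. With
K unknown, the cluster count is estimated by Louvain modularity
optimization (resolution 1.0) on an unweighted symmetric Euclidean
15-nearest-neighbor graph. Because the in-search fitness itself needs a K
for K-means, the pipeline estimates K by Louvain on the full HVG matrix
*before* the search and re-estimates on the selected genes afterward; this
keeps the search objective well-defined without assuming the final K. If
all cells are identical on the selected genes the kNN graph carries no
structure and a single community is returned by construction.

### Validity metrics

RI, ARI, NMI, AMI (arithmetic normalization, exact hypergeometric expected
mutual information), FMI, and ACC. ACC defaults to Hungarian-matched
accuracy — the fraction of cells correctly assigned under the optimal
one-to-one cluster-to-class matching — because a pair-counting "accuracy"
(TP+TN over all pairs) is algebraically the Rand index and therefore
redundant as a separate metric; the pairwise mode is still provided and
its identity with RI is property-tested. Standard implementations
(scikit-learn, SciPy's assignment solver) back these computations; the
test suite checks every metric against independent brute-force pair
enumeration and exact binomial-coefficient arithmetic to 1e−10.

## Synthetic data generator

The generator plants K_true round-robin cell clusters in a negative-
binomial count matrix: informative genes get cluster-specific means
base_mean · 2^(effect·z) with balanced z = ±1/2 assignments per cluster
(so `effect` is the log2 fold separation), noise genes share one mean, and
var = μ + dispersion·μ². Optional uniform Bernoulli dropout zeroes entries.

Defaults: 200 cells, 200 genes, 2 clusters, 20 informative genes,
effect 2, base_mean 5, dispersion 0.2, dropout 0. The default regime
deliberately emulates *clean, well-separated, deeply sequenced* data in
which zeros arise only from the count distribution itself. Two findings
from calibrating this regime are worth recording because they shape what
the tests can and cannot show:

- **Silhouette is deceptive on tiny gene subsets.** On 1–3 genes, K-means
  partitions of essentially any count-valued data form tight 1-D clumps
  with silhouette far above that of the planted 20-gene structure
  (≈0.85 vs ≈0.27 on this fixture). The silhouette+parsimony objective's
  *global* optimum at desk scale is therefore a degenerate mask of one or
  two genes whose partition is unrelated to cell identity. The 30-iteration
  search regime exercised by the tests operates before this collapse;
  longer runs drift toward it. At realistic scale (D ≈ 2000, masks staying
  in the hundreds of genes) the search never reaches this territory.
- **Uniform dropout is adversarial to this objective.** Zeroing entries at
  a flat rate gives every noise gene a strong zero/non-zero bimodality that
  single-gene silhouette rewards; under 20% dropout, deeper optimization
  *lowers* agreement with the planted partition. Dropout therefore defaults
  off; it remains a first-class generator parameter for studying exactly
  this failure mode.

Consequently, passing tests demonstrate the correctness of the machinery
(encoding, dynamics, fitness, metrics, reproducibility) and recovery of
planted structure in a favorable regime — not performance on real
scRNA-seq data, which is sparser, noisier, batch-affected, and has no
ground truth. The generator makes no attempt to model batch effects,
trajectories, doublets, or expression-dependent dropout.

## Reproducibility and numerics

- Every stochastic component draws from one `numpy.random.Generator`
  seeded by the caller; repeated runs use consecutive seeds with one
  independent stream per run, so serial and parallel execution agree.
  Identical (input, config, seed) gives byte-identical output files.
- Louvain uses igraph's multilevel algorithm with an explicitly seeded
  RNG, restored afterward.
- Ties in role assignment, HVG ranking and gene-frequency ranking all
  break deterministically (gene count, then index; score, then index;
  count, then lexicographic id).
- Degenerate inputs are contracts, not crashes: all-zero matrices, zero-
  total cells, empty masks, single-cluster silhouettes and identical cells
  each have a defined error or sentinel behavior, tested.

## Test problem sizes

The suite runs the full search at the default fixture scale (200×200,
population 50) for the planted-structure and convergence checks, and at
reduced scale (e.g. 60 cells × 30 genes, population 12) for stochastic
ordering checks that average over many seeds, chosen so the entire suite
completes in a few minutes on one CPU. The random-search comparison
(Pdp = 1) is an ordering property and is scale-free in its conclusion.

## Known limitations

- The silhouette-parsimony objective degenerates on very small gene
  subsets (above); a minimum-subset-size constraint or a silhouette
  variant penalizing tiny masks would be natural extensions.
- The Case-2/Case-3 split of normal squirrels, the escape distribution,
  and the Lévy step generator are free design choices where the underlying
  recurrences leave them open; different choices change trajectories but
  not the contracts tested here.
- Hungarian ACC and pairwise ACC disagree by design; reports include both
  conventions' values only through the default (Hungarian) plus RI.
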