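# Methods

## Data model and preprocessing

The unit of analysis is a species × VOC matrix of emission intensities in
ncps, with species → family and VOC → chemical-class annotations kept in
separate two-column tables. Replicate sample rows are collapsed to one row
per species by the arithmetic mean. Input is assumed background-corrected
and normalized; no spectrometry-level processing (mass calibration, peak
picking, cps→ncps conversion) is performed here.

Per-VOC descriptive statistics use Tukey's boxplot machinery: quartiles
Q₁, Q₂, Q₃, IQR = Q₃ − Q₁, outlier fences at Q₁ − 1.5·IQR / Q₃ + 1.5·IQR,
and extreme fences at 3·IQR. Quartiles are computed by linear
interpolation of order statistics (quantile type 7) — the most widespread
default, pinned so results are exactly reproducible; Tukey hinges are
available as an option to probe sensitivity of downstream thresholds.
Standardization removes the sample mean and divides by the n−1 standard
deviation.

Two binarization schemes produce the incidence matrix:

* **fixed** — a cell counts iff its emission is *strictly* greater than a
  fixed threshold (1 ncps for a dense graph; 0 ncps to separate any
  emission from none);
* **q3** — per VOC column, a cell counts iff strictly above that column's
  Q₃ across all species, zeros included. Strict inequality means an
  all-zero column marks nothing, and a column with ≥ 75 % zeros can only
  mark its nonzero spikes; this is what makes non-emitting species drop
  out as isolated nodes.

## Graphs

The incidence matrix defines a two-layer plant–VOC graph; both one-mode
projections are computed from it. Projection weights are shared-neighbor
counts (off-diagonals of AAᵀ and AᵀA), so they are integers bounded by
each endpoint's row degree, and the pairwise weight total satisfies
Σᵢⱼ wᵢⱼ = Σ_f C(d_f, 2) — an exact integer identity used as a test.
Isolated nodes are kept in every graph object: their emergence under the
q3 scheme is a finding (species emitting nothing at high level), and
density is reported both with and without them.

Edge weights are rescaled to [0, 1] by min–max normalization over the
existing edges before filtering; if all weights coincide they map to 1 so
that filtering is a no-op. Filtering keeps edges with rescaled weight
**≥** the cutoff (closed, so cutoff 1 retains the maximum-weight edges)
and never drops nodes. Connectivity in sweep rows is evaluated on the
subgraph of non-isolated nodes.

## Metrics

Degree, strength (each undirected edge counted once), density
D = 2E/(N(N−1)), mean degree 2E/V, and the Barrat weighted clustering
coefficient. The clustering coefficient is undefined (reported as NaN,
excluded from CCDF tables) for nodes with fewer than two neighbors,
including isolated nodes, rather than being forced to 0. CCDFs are
evaluated at each distinct observed value as P(X > x).

## Community detection

Modularity is evaluated on the weighted adjacency — A_vw = w_vw, node
degree replaced by strength, m = total edge weight — in the community-sum
form Σᵢ (eᵢᵢ − aᵢ²); the explicit double-sum form is kept as an
independent O(N²) cross-check. An unweighted toggle exists on every
algorithm.

The four algorithms are implemented here, not wrapped:

* **Louvain** (BL): two-phase local moves + aggregation; node visiting
  order is shuffled from the seed, which is the only stochastic element;
  moves require a strict gain (> 1e-12) so each pass is modularity-
  nondecreasing and termination is guaranteed.
* **Fast greedy** (FG, Clauset–Newman–Moore): singleton start, repeated
  merging of the edge-connected pair with the largest ΔQ until no
  connected pair remains (N − 1 merges on a connected graph), cut at the
  maximum-Q step; the merge dendrogram is returned. Ties in ΔQ resolve to
  the first-scanned pair in community-id order, making FG deterministic.
* **Walktrap** (WT, Pons–Latapy): t-step transition profiles (default
  t = 4, the customary walk length) scaled by 1/√d, Ward-style
  agglomeration of adjacent communities minimizing the variance increase,
  dendrogram cut at maximum weighted modularity. Degree-0 nodes are
  excluded from the walk and returned as singletons.
* **Label propagation** (LP): unique initial labels, asynchronous updates
  in seed-shuffled order, votes weighted by edge weight, ties broken
  uniformly from the seed; stops when every node's label is among its
  neighborhood's maximal labels, with a hard cap of 1000 sweeps purely to
  guarantee halting on oscillating inputs.

Isolated nodes end up in singleton communities under every algorithm;
reporting merges them into one trailing "isolated" pseudo-cluster.

An exhaustive maximum-modularity search over all set partitions (refused
above 10 nodes) serves as the oracle for the heuristics. Louvain is a
greedy heuristic and can land in a local optimum on individual tiny
graphs — its near-optimality is therefore a statement about the ensemble
(aggregate Q ≥ 0.95 of the exhaustive aggregate over random ≤ 8-node
graphs, measured ≈ 0.99), not a per-instance guarantee; reference
implementations (igraph's multilevel) show the same per-instance
behavior.

Cross-algorithm consensus computes pairwise ARI/NMI matrices, the set of
node pairs co-clustered by every algorithm, and retains the maximum-Q
partition, flagged robust iff the minimum pairwise ARI reaches a
configurable threshold (default 0.7 — a convention of this package; "the
algorithms agreed" needs an operational cutoff). Stochastic algorithms
default to 10 seeded runs keeping the max-Q result.

## Synthetic generator

Each cell is 0 with probability `p_zero`, otherwise a lognormal plateau
draw (median `plateau_scale` = 0.1 ncps, σ = 0.5); cells whose species
block is affine to the VOC's class additionally gain a heavy-tailed spike
with probability `spike_prob`. Spikes are Pareto (shape 1.5) with floor
10 × plateau_scale = 1 ncps, giving the "few huge emitters" pattern; a
lognormal spike option exists. The default scale mirrors the study
design: 109 species of which 28 emit nothing, three emitting blocks of
37/25/19 species, and a 30-VOC panel (75 in full-panel mode) split among
the blocks proportionally to block size, with block-coherent chemical
classes (terpene fragments, sulfur compounds, ketones/aldehydes).

Default sparsity is `p_zero` = 0.95 and `spike_prob` = 0.6. These place
the generator in the regime the pipeline is designed for — marked cells
per VOC dominated by block spikes rather than plateau noise — which is
required for the planted partition to be the modularity optimum of the
Q3-projection; at substantially denser plateaus (e.g. `p_zero` = 0.8)
cross-block plateau co-marks outweigh the block signal and the true
blocks merge, a useful hard setting for sensitivity studies but not a
sensible default for a generator whose truth is meant to be recoverable.
Silent species are exact-zero rows (they release no protonated mass at
all), which is precisely what makes them degree-0 in every thresholded
projection; giving them low plateau emissions instead would let sparse
columns mark them above Q₃ and blur the isolated set.

What the generator does **not** emulate: instrument noise and drift,
fragmentation patterns shared across masses, correlated emissions between
chemical classes, replicate structure, or species with mixed-block
chemistry (block–VOC affinity is many-to-one). Passing recovery tests
therefore show that the pipeline is correct and well-calibrated on
block-structured heavy-tailed matrices, not that real botanical data
carry as clean a signal.

## Numerical conventions

* Threshold comparisons are strict (>); edge filtering is closed (≥).
* Quantiles: type 7; an exact-equality oracle test pins the estimator.
* Modularity comparisons in tests use 1e-12 absolute tolerance; algorithm
  gain thresholds use 1e-12 so float noise cannot cause move cycling.
* Rank tie-breaks (top-strength lists, family histograms) are
  alphabetical after the primary sort key, making every report
  deterministic.
* Percentages are rounded half-up to one decimal.
* Degenerate inputs: edgeless graphs refuse modularity/rescaling; an
  empty VOC selection yields a 0-column matrix that fails at graph build;
  constant series refuse standardization.

## Problem sizes

The validation suite runs at the study scale (109 × 30 matrices, 81-node
active projections) and uses 100 random graphs of 4–14 nodes for oracle
equivalence, 100 graphs of ≤ 8 nodes against exhaustive search, and 20
generator seeds (each with 10 Louvain seeds) for planted recovery; the
whole suite completes in a few seconds on one CPU.

## Known limitations

* Fast greedy is the O(N³)-ish textbook agglomeration, fine for a few
  hundred nodes, not for large graphs.
* Walktrap stores dense N × N transition matrices.
* Only the two one-mode projections are supported, no general k-mode
  projections, no overlapping or resolution-parameterized community
  models.
* Published per-row edge counts of the original filtering sweep depend on
  raw data that were never deposited; the sweep reproduces the procedure
  and column semantics, not those exact counts.
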