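# Methods

## Problem and model

Expression studies of the "large p, small n" kind (tens of samples, hundreds
to tens of thousands of genes) need gene subsets that are small, stable and
informative for class prediction. `isoga` implements a wrapper selection
method built on three ideas:

1. **Manifold-aware subset scoring.** A candidate subset s of m genes is
   scored by embedding the samples restricted to those genes with Isomap —
   k-nearest-neighbour graph with Euclidean edge weights, union
   symmetrization, all-pairs shortest-path (Floyd–Warshall) geodesic
   distances, classical MDS of the geodesic matrix — and computing the
   Davies–Bouldin (DB) index of the embedded points against the class
   labels:

       F(s) = DB(Isomap_d(X^(s)), y),
       DB   = (1/C) Σ_i max_{j≠i} (S_i + S_j) / ‖μ_i − μ_j‖,

   with μ_i the class centroid and S_i the mean distance of class-i points
   to it.  Lower DB = clearer class division.  Using a cluster-validity
   index instead of a classifier's accuracy avoids classifier dependency;
   using geodesic rather than Euclidean distances respects a curved
   expression manifold.

2. **Fixed-cardinality genetic search.** Subsets are binary strings with
   exactly m ones (default m = 30), searched by a GA whose operators
   conserve cardinality: crossover keeps the parents' intersection and
   fills the rest uniformly from the symmetric difference; mutation swaps a
   selected index for an unselected one.  Tournament selection (size 2)
   minimizes F, with one elite.  After the final generation the 10 best
   distinct subsets are re-ranked by the out-of-bag accuracy of a
   fixed-hyperparameter RBF-SVM, and the winner becomes that run's optimum.

3. **Binomial aggregation across bootstrap bags.** The search is repeated
   on B = 10 stratified bootstrap bags.  Under pure chance each search
   includes a given gene with probability p = m/n_gene, so the count X of a
   gene across B searches is Binomial(B, p).  The inclusion threshold c is
   the smallest count with P(X ≥ c) < α (default α = 0.05), floored at 2 —
   a gene seen once is never distinguishable from chance.  The final set is
   s_best = {g : count(g) ≥ c}.  For B = 10, m = 30, α = 0.05 this gives
   c = 2 for pools of ~1000+ genes, rising to 8 at a pool of 70.

## Parameter selection

* **Embedding dimension d** is estimated once per training set with the
  Levina–Bickel maximum-likelihood estimator: per point,
  m̂_k(x) = [(1/(k−1)) Σ_{j<k} ln(T_k/T_j)]⁻¹ over neighbour distances T_j;
  local estimates are combined by averaging their inverses, then averaged
  over k in [5, 12] and rounded.  The result is capped at
  min(n − 2, m − 1).  On noise-heavy matrices the estimator reads high and
  the cap binds; that is intentional — d must stay below the subset size.
* **Neighbourhood size k** is grid-searched over [5, 20] (clipped to
  n − 1), keeping the k whose Isomap embedding of the full training matrix
  has the smallest DB index.  k values with disconnected graphs are
  skipped; a subset whose graph disconnects during GA scoring receives +∞
  fitness, so the search avoids it rather than silently embedding one
  component (which would change n between candidates and make DB values
  incomparable).
* **Classifier grids.** The final RBF-SVM is tuned over kernel width
  sigma ∈ {0.001, 0.011, …, 0.091} (the rbfdot convention
  k = exp(−sigma‖x−y‖²); sklearn's `gamma`) and cost 1..10; the
  two-hidden-layer network over (10..30 step 2) × (4..20 step 2) nodes.
  Each grid point is scored by mean accuracy over two 3-fold stratified
  cross-validations; ties go to the first grid point.

## Evaluation protocol

Outer stratified 5-fold cross-validation.  Standardization parameters are
learned on the training folds only and applied to the test fold, and the
zero-information-gain filter is fitted on training data, so no test
statistic leaks into selection or tuning; an audit trail records the index
sets used at each stage and `audit_leakage` verifies disjointness
mechanically.  Metrics: accuracy, macro-AUC (unweighted mean of one-vs-rest
AUCs) and micro-AUC (AUC of the pooled (sample, class) indicator/score
pairs).  Note the pooled micro-AUC is a genuinely different statistic from
the binary AUC even for C = 2 — they track each other closely but are not
identical pair-for-pair.  Method comparison uses a ranking score: within
each (dataset, metric) cell methods receive average ranks (1 = best), and
within each dataset they are ranked by subset size (1 = smallest); a
method's score is the sum of all its ranks, lower = better.

## Preprocessing

Fixed order: genes with missing values dropped → constant genes dropped →
per-gene standardization (sample sd, n−1, configurable) → removal of genes
with zero information gain about the label.  IG uses Fayyad–Irani MDL
binary-recursive discretization (base-2 entropy): when no cut point passes
the MDL acceptance test the gene's IG is exactly 0, which is what lets the
filter remove large numbers of noise genes outright.  An equal-frequency
10-bin discretizer is available as a configurable alternative; it almost
never yields exact zeros, so it effectively disables the filter — useful
when the pool must stay larger than the subset size.  Outlier samples are
flagged (count of |z| > 6 entries per sample) but never removed
automatically, since no defensible automatic rule presented itself.

## Synthetic data

The generator emulates the target regime: n = 60 samples, p = 300 genes,
C = 2 classes, 10 informative genes, the rest independent N(0, 1) noise.
Each class occupies a disjoint interval (gap 0.3) of a curve parameter t;
each informative gene is a monotone arc of a random-frequency sine
(`swiss_roll_arcs`; amplitude 1.5, frequencies chosen so the arc stays
monotone over the t-range) or a monotone cubic (`s_curve_arcs`), plus
N(0, σ) noise with σ = 0.1 by default.  Monotone lifts guarantee that the
classes occupy disjoint value ranges per informative gene, so planted genes
carry positive information gain and the class structure is recoverable;
distinct frequencies/phases make the informative block a curved (not
straight) 1-D manifold.  `gaussian_linear` plants plain mean shifts for
linear-separability checks.  What the generator does **not** emulate:
probe-level artifacts, batch effects, gene–gene correlation among noise
genes, heavy-tailed expression distributions.  Passing recovery tests shows
the machinery finds planted low-dimensional class structure at realistic
n/p; it does not certify performance on real microarray cohorts.

## Numerical choices

* Classical MDS: K = −½ J D² J; eigen-decomposition; negative eigenvalues
  clamped to 0 before the square root; each eigenvector's largest-magnitude
  entry is made positive (reproducible signs); requesting more dimensions
  than positive eigenvalues pads with zeros and warns.
* k-NN ties break by lower point index (stable argsort); all subset ties in
  the GA break lexicographically; each bootstrap bag runs on its own RNG
  stream seeded master_seed + bag_index, so runs are bit-reproducible.
* Fitness values are memoized per sorted index tuple within a search; NaN
  fitness is treated as +∞ with a warning.
* DB returns +∞ when two class centroids coincide with nonzero scatter
  (0/0 between coincident singletons counts as 0).

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` exercise the framework at sizes
a laptop handles in minutes: recovery experiments on the n = 60, p = 300
benchmark draw with GA budget population 30 × 30 generations × 10 bags;
nested CV on n = 40, p = 60 with reduced grids; oracle checks (shortest
paths, MDS, DB) on hundreds of small random instances.  The defaults in
`RunConfig` (population 100, 100 generations) are the recommended operating
point for real analyses.

## Known limitations

* Isomap has no out-of-sample extension here; embeddings are recomputed per
  candidate subset, which is the dominant cost (O(n³) per evaluation).
* The binomial threshold assumes independent, equal-probability selection
  under the null; correlated genes violate independence, so c is a
  heuristic guard, not an exact test.
* MLDE is biased upward when measurement noise dominates the local
  neighbour spacing; the cap keeps this harmless for the search but the
  reported d should not be read as the true manifold dimension in that
  regime.
* With B = 1 bag the floored threshold c ≥ 2 can exceed the maximum
  possible count; s_best is then legitimately empty (warned, not raised).
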