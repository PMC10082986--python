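# isoga

Manifold-aware genetic-algorithm gene selection for expression data.

## The problem

Microarray and bulk expression studies live in the "large p, small n"
regime: tens of samples, thousands of genes, and only a handful of genes
actually informative for the phenotype.  Wrapper feature selection — search
over candidate gene subsets, score each subset — works well here, but two
things routinely go wrong: the score depends on a particular classifier,
and stochastic search returns a different subset every run.  `isoga`
addresses both for analysts who need small, stable, interpretable gene
panels.

## The method

A candidate subset **s** of m genes (default m = 30) is scored
classifier-free by the Davies–Bouldin index of its Isomap embedding:

    F(s) = DB(Isomap_d(X^(s)), y),      DB = (1/C) Σ_i max_{j≠i} (S_i+S_j)/‖μ_i−μ_j‖

where Isomap embeds the samples via geodesic (k-NN shortest-path) distances
and classical MDS, μ_i and S_i are class centroids and mean within-class
scatters, and lower DB means clearer class separation.  A
fixed-cardinality genetic algorithm minimizes F; the search is repeated on
B = 10 stratified bootstrap bags, each run's winner being the subset (among
the 10 fittest) with the best out-of-bag SVM accuracy.  A gene enters the
final set s_best only if it was selected at least c times, where c is the
smallest count that is a < 5% tail event under Binomial(B, m/n_gene) —
i.e. the gene's recurrence cannot be explained by search randomness.
Linear (classical-MDS) and no-embedding ablations, nested cross-validation
with macro-/micro-AUC, and a rank-based method comparison are included.

## Worked example

```python
import numpy as np
from isoga import RunConfig, SimSpec, generate, iso_ga_select, standardize

# synthetic benchmark: 60 samples, 300 genes, 10 informative genes lying
# on a class-separating nonlinear curve, the rest Gaussian noise
ds, truth = generate(SimSpec(n=60, p=300, m_info=10, seed=1))
std, _ = standardize(ds)

config = RunConfig(pop_size=30, generations=30, bags=10, seed=11)
result = iso_ga_select(std.matrix, std.labels, config, gene_ids=std.gene_ids)

print(f"tuned k = {result.k}, embedding dimension d = {result.d}")
print(f"inclusion threshold c = {result.threshold.c} "
      f"(B = {result.n_bags} bags, alpha = {result.threshold.alpha})")
print(f"selected {len(result.s_best)} genes: {result.best_gene_ids()}")
planted = {ds.gene_ids[i] for i in truth}
hits = planted.intersection(result.best_gene_ids())
print(f"{len(hits)} of {len(result.s_best)} selected genes are planted informative genes")
```

prints

```
tuned k = 5, embedding dimension d = 29
inclusion threshold c = 4 (B = 10 bags, alpha = 0.05)
selected 11 genes: ['g0099', 'g0107', 'g0131', 'g0154', 'g0163', 'g0182', 'g0220', 'g0223', 'g0233', 'g0260', 'g0275']
9 of 11 selected genes are planted informative genes
```

The neighbourhood size k = 5 minimized the DB index over the grid 5..20;
the embedding dimension hit its cap (m − 1 = 29) because the
maximum-likelihood estimator reads high on noise-dominated matrices; and
with 300 genes a gene must recur in at least c = 4 of the 10 bagged
searches to beat chance.  Of the 11 genes passing that bar, 9 are truly
informative — the search recovers the planted panel with high precision
from 30× more noise genes than signal genes.

The same pipeline is available from the shell:

```bash
isoga simulate --n 60 --p 300 --m-info 10 --seed 1 --out-dir data/
isoga select --expression data/expression.csv --seed 11 --out-dir run/
isoga evaluate --expression data/expression.csv --out-dir eval/
```

Each command writes a JSON run manifest (input checksums, resolved
configuration, seed) so any run can be replayed exactly.

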