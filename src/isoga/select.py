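"""Orchestration of the gene-selection framework.

One selection run on a training set proceeds as:

1. estimate the embedding dimension d on the full (filtered) gene matrix;
2. grid-search the Isomap neighbourhood size k by minimal DB index;
3. draw B stratified bootstrap bags of the training samples;
4. per bag, run the fixed-cardinality GA minimizing the DB index of the
   embedded candidate subset, then pick among the 10 best subsets of the
   final generation the one with the highest out-of-bag SVM accuracy;
5. count how often each gene appears across the B per-bag optima and keep
   the genes whose count exceeds a binomial non-randomness threshold.

The threshold treats each of the B searches as a Bernoulli trial in which
a gene is picked with probability m/p under pure chance, and admits a gene
only when its selection count would be a < alpha tail event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.svm import SVC
from scipy.spatial.distance import pdist

from .cluster_validity import SubsetFitness
from .datasets import RunConfig
from .ga import GAState, Individual, evolve, init_population, top_k
from .manifold import estimate_intrinsic_dim, tune_k

log = logging.getLogger(__name__)


@dataclass
class ThresholdSpec:
    """Binomial model of chance selection across repeated searches."""

    n_gene: int
    v: int = 30
    runs: int = 10
    alpha: float = 0.05
    c: int | None = None

    @property
    def p_select(self) -> float:
        return self.v / self.n_gene


@dataclass
class SelectionResult:
    """Everything a selection run produced, enough to replay or report it."""

    bag_subsets: list[Individual]
    counts: dict[int, int]
    threshold: ThresholdSpec
    s_best: list[int]
    k: int | None
    d: int | None
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    bag_seeds: list[int] = field(default_factory=list)

    @property
    def n_bags(self) -> int:
        return len(self.bag_subsets)

    def best_gene_ids(self) -> list[str]:
        if not self.gene_ids:
            return [str(i) for i in self.s_best]
        return [self.gene_ids[i] for i in self.s_best]


def selection_threshold(spec: ThresholdSpec) -> int:
    """Smallest count c with P(X >= c) < alpha, X ~ Binom(runs, v/n_gene).

    Floored at 2: a gene seen once can never be distinguished from chance.
    If even c = runs fails the bound (selection probability too high),
    returns runs + 1 with a warning — no gene can qualify.
    """
    if spec.n_gene < spec.v:
        raise ValueError(f"n_gene={spec.n_gene} smaller than subset size v={spec.v}")
    p = spec.p_select
    for c in range(1, spec.runs + 1):
        if binom.sf(c - 1, spec.runs, p) < spec.alpha:
            spec.c = max(c, 2)
            return spec.c
    log.warning(
        "no count c <= %d reaches the alpha=%.3g bound (p=%.3g): "
        "no gene can be declared non-random",
        spec.runs, spec.alpha, p,
    )
    spec.c = spec.runs + 1
    return spec.c


def _median_gamma(X: np.ndarray) -> float:
    """RBF width by the median-distance heuristic: gamma = 1/(2 σ_med²)."""
    d = pdist(X)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med * med)


def _oob_accuracy(subset: Individual, X_in, y_in, X_oob, y_oob) -> float:
    cols = list(subset)
    Xi, Xo = X_in[:, cols], X_oob[:, cols]
    clf = SVC(kernel="rbf", C=1.0, gamma=_median_gamma(Xi))
    clf.fit(Xi, y_in)
    return float((clf.predict(Xo) == y_oob).mean())


def run_single_search(
    X_inbag: np.ndarray,
    y_inbag: np.ndarray,
    X_oob: np.ndarray,
    y_oob: np.ndarray,
    k: int | None,
    d: int | None,
    config: RunConfig,
    rng: np.random.Generator,
) -> Individual:
    """One GA search on a bag, validated on the out-of-bag samples.

    The GA minimizes the DB index of the embedded candidate subset on the
    in-bag samples; among the 10 best distinct subsets of the final
    generation, the one with the highest out-of-bag accuracy of a
    fixed-hyperparameter RBF-SVM wins (ties: lower DB, then lexicographic
    order).  If the out-of-bag set holds a single class, the best-fitness
    subset is returned directly.
    """
    fitness = SubsetFitness(X_inbag, y_inbag, k, d, mode=config.embedding)
    state = init_population(X_inbag.shape[1], config.subset_size, config.pop_size, rng)
    state = evolve(
        state,
        fitness,
        generations=config.generations,
        tournament_size=config.tournament_size,
        elitism=config.elitism,
        mutation_rate=config.mutation_rate,
    )
    candidates = top_k(state, min(config.validation_top, config.pop_size))
    if np.unique(y_oob).size < 2:
        log.warning("out-of-bag set has a single class; returning best-fitness subset")
        return candidates[0][0]
    ranked = sorted(
        candidates,
        key=lambda t: (-_oob_accuracy(t[0], X_inbag, y_inbag, X_oob, y_oob), t[1], t[0]),
    )
    return ranked[0][0]


def iso_ga_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RunConfig | None = None,
    gene_ids: list[str] | None = None,
) -> SelectionResult:
    """Full bagged selection on a preprocessed training matrix.

    Returns the per-bag optima, gene selection counts, the binomial
    inclusion threshold and the final gene set s_best = {g : count(g) >= c}.
    s_best may legitimately come back empty (warning, not an exception);
    callers can lower alpha or add bags.
    """
    config = config or RunConfig()
    config.validate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    n, p = X_train.shape

    d: int | None = None
    k: int | None = None
    if config.embedding in ("isomap", "mds"):
        d = estimate_intrinsic_dim(
            X_train,
            neighbor_range=config.mlde_range,
            max_dim=min(n - 2, config.subset_size - 1),
        )
        log.info("estimated intrinsic dimension d=%d", d)
    if config.embedding == "isomap":
        k = tune_k(X_train, y_train, d, config.k_range)
        log.info("tuned neighbourhood size k=%d", k)

    from .evaluate import stratified_bootstrap  # deferred: evaluate imports select

    master = np.random.default_rng(config.seed)
    bags = stratified_bootstrap(y_train, B=config.bags, rng=master)

    bag_subsets: list[Individual] = []
    bag_seeds: list[int] = []
    for b, (in_bag, oob) in enumerate(bags):
        seed_b = config.seed + b
        bag_seeds.append(seed_b)
        rng_b = np.random.default_rng(seed_b)
        s_opt = run_single_search(
            X_train[in_bag], y_train[in_bag],
            X_train[oob], y_train[oob],
            k, d, config, rng_b,
        )
        log.info("bag %d/%d: optimal subset found", b + 1, config.bags)
        bag_subsets.append(s_opt)

    counts: dict[int, int] = {}
    for s in bag_subsets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1

    spec = ThresholdSpec(n_gene=p, v=config.subset_size,
                         runs=config.bags, alpha=config.alpha)
    c = selection_threshold(spec)
    s_best = sorted(g for g, cnt in counts.items() if cnt >= c)
    if not s_best:
        log.warning("s_best is empty at threshold c=%d; consider lowering alpha", c)
    return SelectionResult(
        bag_subsets=bag_subsets,
        counts=counts,
        threshold=spec,
        s_best=s_best,
        k=k,
        d=d,
        seed=config.seed,
        gene_ids=gene_ids or [],
        bag_seeds=bag_seeds,
    )
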