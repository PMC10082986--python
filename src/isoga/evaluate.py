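"""Nested cross-validation, stratified splitters, classification metrics
and the ranking score for method comparison.

The outer loop is stratified 5-fold cross-validation; inside each training
portion the selection framework runs on stratified bootstrap bags, final
classifiers are tuned by repeated 3-fold cross-validation on the selected
genes, and the untouched test fold yields accuracy plus macro-/micro-AUC.
An audit trail records which sample indices entered selection and tuning
so leakage into the test fold can be checked mechanically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datasets import ExpressionDataset, RunConfig
from .preprocess import filter_zero_ig, standardize
from .select import SelectionResult, iso_ga_select

log = logging.getLogger(__name__)

# Default classifier tuning grids: RBF-SVM kernel width (the rbfdot sigma
# convention, k = exp(-sigma |x-y|^2)) and cost; two hidden-layer sizes for
# the neural network.
SVM_GRID = [
    {"sigma": s, "cost": c}
    for s in [round(0.001 + 0.010 * i, 3) for i in range(10)]
    for c in range(1, 11)
]
NN_GRID = [
    {"hn1": h1, "hn2": h2}
    for h1 in range(10, 31, 2)
    for h2 in range(4, 21, 2)
]


def make_svm(params: dict, random_state: int = 0) -> SVC:
    return SVC(kernel="rbf", gamma=params["sigma"], C=params["cost"],
               probability=True, random_state=random_state)


def make_nn(params: dict, random_state: int = 0) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(params["hn1"], params["hn2"]),
        max_iter=500,
        random_state=random_state,
    )


def stratified_kfold(
    labels: Sequence[int], folds: int = 5, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Class-wise shuffled round-robin fold assignment.

    Every fold's class proportions sit within one sample of the population
    proportions; the folds partition the sample index set.
    """
    labels = np.asarray(labels)
    rng = rng or np.random.default_rng()
    assignment = np.empty(len(labels), dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < folds:
            raise ValueError(
                f"class {c} has {idx.size} samples, fewer than {folds} folds"
            )
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (offset + pos) % folds
        offset += idx.size  # continue round-robin so remainders spread out
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def stratified_bootstrap(
    labels_train: Sequence[int], B: int = 10, rng: np.random.Generator | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-class resampling with replacement; B (in_bag, out_of_bag) pairs.

    Each class is resampled to its own size so the in-bag multiset has
    exactly the training-set size and composition; the unsampled indices
    form the out-of-bag validation set.  Emits a warning if some sample
    never enters any in-bag set across the B bags.
    """
    labels_train = np.asarray(labels_train)
    if np.unique(labels_train).size < 2:
        raise ValueError("stratified bootstrap needs at least 2 classes")
    rng = rng or np.random.default_rng()
    bags: list[tuple[np.ndarray, np.ndarray]] = []
    ever_in = np.zeros(len(labels_train), dtype=bool)
    for _ in range(B):
        in_parts = []
        for c in np.unique(labels_train):
            idx = np.flatnonzero(labels_train == c)
            in_parts.append(rng.choice(idx, size=idx.size, replace=True))
        in_bag = np.concatenate(in_parts)
        oob = np.setdiff1d(np.arange(len(labels_train)), in_bag)
        if oob.size == 0:
            log.warning("a bag has an empty out-of-bag set")
        for c in np.unique(labels_train):
            if not np.any(np.isin(oob, np.flatnonzero(labels_train == c))):
                log.debug("class %s absent from an out-of-bag set", c)
        ever_in[np.unique(in_bag)] = True
        bags.append((in_bag, oob))
    if not ever_in.all():
        log.warning(
            "%d sample(s) never entered any in-bag set across %d bags",
            int((~ever_in).sum()), B,
        )
    return bags


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Fraction of correctly predicted samples (multiclass: Σ tp_i / n)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float((y_true == y_pred).mean())


def macro_micro_auc(
    y_true: Sequence[int], scores: np.ndarray
) -> tuple[float, float]:
    """One-vs-rest AUC, macro- and micro-averaged.

    Macro: unweighted mean of the per-class one-vs-rest AUCs.  Micro: AUC
    over the pooled (sample, class) indicator/score pairs.  Classes absent
    from ``y_true`` are excluded from the macro mean with a warning.  For
    two complementary probability columns the two averages coincide with
    the ordinary binary AUC.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    classes = np.arange(1, scores.shape[1] + 1)
    per_class = []
    indicator = np.zeros_like(scores)
    for j, c in enumerate(classes):
        mask = y_true == c
        indicator[:, j] = mask
        if mask.any() and not mask.all():
            per_class.append(roc_auc_score(mask, scores[:, j]))
        else:
            log.warning("class %s absent (or exhaustive) in y_true; "
                        "excluded from macro-AUC", c)
    if not per_class:
        raise ValueError("no class admits a one-vs-rest AUC")
    macro = float(np.mean(per_class))
    micro = float(roc_auc_score(indicator.ravel(), scores.ravel()))
    return macro, micro


def tune_classifier(
    X: np.ndarray,
    y: np.ndarray,
    factory: Callable[[dict], object],
    grid: list[dict],
    repeats: int = 2,
    folds: int = 3,
    rng: np.random.Generator | None = None,
) -> dict:
    """Grid search by mean accuracy over ``repeats`` x ``folds`` stratified
    CV; ties go to the first grid point; grid points that fail to train
    score 0."""
    if not grid:
        raise ValueError("empty grid")
    rng = rng or np.random.default_rng()
    plans = [stratified_kfold(y, folds=folds, rng=rng) for _ in range(repeats)]
    best_params, best_score = grid[0], -1.0
    for params in grid:
        scores = []
        for plan in plans:
            for f, test_idx in enumerate(plan):
                train_idx = np.concatenate([plan[g] for g in range(folds) if g != f])
                try:
                    clf = factory(params)
                    clf.fit(X[train_idx], y[train_idx])
                    scores.append(accuracy(y[test_idx], clf.predict(X[test_idx])))
                except Exception as exc:  # noqa: BLE001 - scored 0, logged
                    log.warning("grid point %s failed: %s", params, exc)
                    scores.append(0.0)
        mean = float(np.mean(scores))
        if mean > best_score:
            best_params, best_score = params, mean
    return best_params


@dataclass
class FoldOutcome:
    fold: int
    selection: SelectionResult
    metrics: dict[str, dict[str, float]]      # classifier -> metric -> value
    n_selected: int
    test_indices: np.ndarray
    train_indices: np.ndarray


@dataclass
class EvaluationResult:
    folds: list[FoldOutcome]
    table: pd.DataFrame
    audit: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.table.groupby("classifier")[
            ["accuracy", "macro_auc", "micro_auc", "n_selected"]
        ].agg(["mean", "std"])


def nested_cv_evaluate(
    ds: ExpressionDataset,
    config: RunConfig | None = None,
    svm_grid: list[dict] | None = None,
    nn_grid: list[dict] | None = None,
    binning: str = "mdl",
) -> EvaluationResult:
    """Outer stratified k-fold evaluation of the selection framework.

    Per fold: standardize with training statistics, filter zero-IG genes on
    the training portion, select genes, tune and train the final
    classifiers on the selected genes, and score the untouched test fold.
    The audit list records, per fold, every sample index used for
    selection/tuning and the test indices, for a mechanical leakage check.
    """
    config = config or RunConfig()
    config.validate()
    svm_grid = svm_grid if svm_grid is not None else SVM_GRID
    nn_grid = nn_grid if nn_grid is not None else NN_GRID
    rng = np.random.default_rng(config.seed)
    plan = stratified_kfold(ds.labels, folds=config.outer_folds, rng=rng)
    outcomes: list[FoldOutcome] = []
    audit: list[dict] = []
    rows = []
    for f, test_idx in enumerate(plan):
        train_idx = np.concatenate(
            [plan[g] for g in range(config.outer_folds) if g != f]
        )
        log.info("outer fold %d/%d: %d train, %d test",
                 f + 1, config.outer_folds, train_idx.size, test_idx.size)
        train_ds = ds.subset_samples(train_idx)
        test_ds = ds.subset_samples(test_idx)
        train_std, params = standardize(train_ds)
        test_std = test_ds.subset_genes(range(test_ds.p))
        test_std.matrix = params.apply(test_ds.matrix)
        train_filt, _ = filter_zero_ig(train_std, binning=binning)
        kept = [train_std.gene_ids.index(g) for g in train_filt.gene_ids]
        test_filt = test_std.subset_genes(kept)

        fold_config = RunConfig(**{**config.__dict__, "seed": config.seed + 1000 * f})
        selection = iso_ga_select(
            train_filt.matrix, train_filt.labels, fold_config,
            gene_ids=train_filt.gene_ids,
        )
        audit.append({
            "fold": f,
            "test_indices": set(test_idx.tolist()),
            "selection_indices": set(train_idx.tolist()),
            "tuning_indices": set(train_idx.tolist()),
        })
        metrics: dict[str, dict[str, float]] = {}
        if not selection.s_best:
            log.warning("fold %d: empty s_best, metrics recorded as missing", f)
            for name in ("svm", "nn"):
                metrics[name] = {"accuracy": np.nan, "macro_auc": np.nan,
                                 "micro_auc": np.nan}
        else:
            Xtr = train_filt.matrix[:, selection.s_best]
            Xte = test_filt.matrix[:, selection.s_best]
            for name, factory, grid in (
                ("svm", make_svm, svm_grid),
                ("nn", make_nn, nn_grid),
            ):
                best = tune_classifier(
                    Xtr, train_filt.labels, factory, grid,
                    rng=np.random.default_rng(fold_config.seed + 7),
                )
                clf = factory(best)
                clf.fit(Xtr, train_filt.labels)
                proba = clf.predict_proba(Xte)
                pred = np.asarray(clf.classes_)[np.argmax(proba, axis=1)]
                macro, micro = macro_micro_auc(test_filt.labels, _align_proba(
                    proba, clf.classes_, ds.n_classes))
                metrics[name] = {
                    "accuracy": accuracy(test_filt.labels, pred),
                    "macro_auc": macro,
                    "micro_auc": micro,
                }
        for name, m in metrics.items():
            rows.append({"fold": f, "classifier": name, **m,
                         "n_selected": len(selection.s_best)})
        outcomes.append(FoldOutcome(
            fold=f, selection=selection, metrics=metrics,
            n_selected=len(selection.s_best),
            test_indices=test_idx, train_indices=train_idx,
        ))
    table = pd.DataFrame(rows)
    return EvaluationResult(folds=outcomes, table=table, audit=audit)


def _align_proba(proba: np.ndarray, classes: np.ndarray, n_classes: int) -> np.ndarray:
    """Expand a probability matrix to columns 1..C (absent classes get 0)."""
    out = np.zeros((proba.shape[0], n_classes))
    for j, c in enumerate(np.asarray(classes, dtype=int)):
        out[:, c - 1] = proba[:, j]
    return out


def audit_leakage(result: EvaluationResult) -> bool:
    """True iff no test index ever entered selection or tuning in any fold."""
    for entry in result.audit:
        used = entry["selection_indices"] | entry["tuning_indices"]
        if entry["test_indices"] & used:
            return False
    return True


def ranking_score(
    metric_values: pd.DataFrame,
    subset_sizes: pd.DataFrame,
) -> pd.Series:
    """Composite rank of competing methods over datasets and metrics.

    ``metric_values``: methods in rows, (dataset, metric) MultiIndex
    columns, higher = better.  ``subset_sizes``: methods x datasets,
    smaller = better.  Within each column, methods get average ranks (1 =
    best).  A method's score is the sum of all its metric ranks plus the
    sum of its size ranks; lower is better.  Missing cells are ranked over
    the methods present in that column, with a warning.
    """
    if metric_values.shape[0] < 2:
        raise ValueError("need at least 2 methods to rank")
    total = pd.Series(0.0, index=metric_values.index)
    for col in metric_values.columns:
        vals = metric_values[col]
        present = vals.notna()
        if not present.all():
            log.warning("missing metric cell(s) in %s: pairwise-complete ranking", col)
        ranks = rankdata(-vals[present].to_numpy(), method="average")
        total[present.index[present]] += ranks
    for col in subset_sizes.columns:
        vals = subset_sizes[col]
        present = vals.notna()
        ranks = rankdata(vals[present].to_numpy(), method="average")
        total[present.index[present]] += ranks
    return total
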