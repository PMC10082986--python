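"""Splitters, metrics, classifier tuning, nested CV and ranking scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from isoga.datasets import ExpressionDataset, RunConfig
from isoga.evaluate import (
    accuracy,
    audit_leakage,
    macro_micro_auc,
    make_svm,
    nested_cv_evaluate,
    ranking_score,
    stratified_bootstrap,
    stratified_kfold,
    tune_classifier,
)
from isoga.simulate import SimSpec, generate


class TestStratifiedKFold:
    def test_exact_divisibility(self, rng):
        labels = np.array([1] * 40 + [2] * 20)
        folds = stratified_kfold(labels, folds=5, rng=rng)
        for fold in folds:
            assert (labels[fold] == 1).sum() == 8
            assert (labels[fold] == 2).sum() == 4

    def test_partition_and_rounding_bound(self, rng):
        labels = np.array([1] * 7 + [2] * 5)
        folds = stratified_kfold(labels, folds=5, rng=rng)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(12))
        for fold in folds:
            for c, total in ((1, 7), (2, 5)):
                got = (labels[fold] == c).sum()
                assert abs(got - total / 5) <= 1

    def test_determinism(self):
        labels = np.array([1] * 10 + [2] * 10)
        a = stratified_kfold(labels, 5, np.random.default_rng(3))
        b = stratified_kfold(labels, 5, np.random.default_rng(3))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_small_class_raises(self, rng):
        labels = np.array([1] * 10 + [2] * 3)
        with pytest.raises(ValueError, match="2"):
            stratified_kfold(labels, folds=5, rng=rng)


class TestStratifiedBootstrap:
    def test_per_class_resampling_sizes(self, rng):
        labels = np.array([1] * 40 + [2] * 20)
        for in_bag, oob in stratified_bootstrap(labels, B=5, rng=rng):
            assert in_bag.size == 60
            assert (labels[in_bag] == 1).sum() == 40
            assert (labels[in_bag] == 2).sum() == 20
            assert np.intersect1d(np.unique(in_bag), oob).size == 0

    def test_oob_fraction_near_e_inverse(self):
        labels = np.array([1] * 30 + [2] * 30)
        rng = np.random.default_rng(8)
        fractions = [
            oob.size / 60
            for in_bag, oob in stratified_bootstrap(labels, B=200, rng=rng)
        ]
        # per-sample OOB probability (1 - 1/n)^n -> e^-1
        expect = (1 - 1 / 30) ** 30
        sigma = np.sqrt(expect * (1 - expect) / 60) / np.sqrt(200)
        assert abs(np.mean(fractions) - expect) < 3 * sigma + 0.01

    def test_all_samples_seen_across_ten_bags(self):
        labels = np.array([1] * 40 + [2] * 20)
        rng = np.random.default_rng(4)
        bags = stratified_bootstrap(labels, B=10, rng=rng)
        ever = np.zeros(60, dtype=bool)
        for in_bag, _ in bags:
            ever[np.unique(in_bag)] = True
        assert ever.all()

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            stratified_bootstrap(np.ones(10, dtype=int), rng=rng)


class TestMetrics:
    def test_accuracy_formula(self):
        # TP=3, TN=4 among P=5, N=5
        y_true = np.array([1] * 5 + [2] * 5)
        y_pred = np.array([1, 1, 1, 2, 2, 2, 2, 2, 2, 1])
        assert accuracy(y_true, y_pred) == pytest.approx(0.7)

    def test_accuracy_multiclass(self):
        y_true = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3])
        y_pred = np.array([1, 1, 2, 2, 2, 3, 3, 3, 1, 2])
        assert accuracy(y_true, y_pred) == pytest.approx(0.6)

    def test_accuracy_empty_raises(self):
        with pytest.raises(ValueError):
            accuracy([], [])

    def test_perfect_ranking(self):
        y = np.array([1, 1, 2, 2])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert macro_micro_auc(y, scores) == (1.0, 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        n = 2000
        y = rng.integers(1, 4, size=n)
        raw = rng.random((n, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        macro, micro = macro_micro_auc(y, scores)
        # 3 sigma of a null AUC is ~ sqrt(1/12)/sqrt(n) scaled; generous band
        assert abs(macro - 0.5) < 0.05 and abs(micro - 0.5) < 0.05

    def test_binary_macro_equals_standard_micro_close(self, rng):
        # macro over two complementary columns is exactly the binary AUC;
        # the pooled micro ranking is a distinct statistic that tracks it
        # closely but is not identical pair-for-pair
        y = rng.integers(1, 3, size=100)
        p1 = rng.random(100)
        scores = np.column_stack([1 - p1, p1])
        macro, micro = macro_micro_auc(y, scores)
        ref = roc_auc_score(y == 2, p1)
        assert macro == pytest.approx(ref, abs=1e-12)
        assert micro == pytest.approx(ref, abs=0.02)

    def test_reversed_scores_complement(self, rng):
        y = rng.integers(1, 3, size=60)
        p1 = rng.random(60)
        fwd = macro_micro_auc(y, np.column_stack([1 - p1, p1]))[0]
        rev = macro_micro_auc(y, np.column_stack([p1, 1 - p1]))[0]
        assert fwd == pytest.approx(1 - rev, abs=1e-12)

    def test_non_finite_scores_raise(self):
        with pytest.raises(ValueError):
            macro_micro_auc(np.array([1, 2]), np.array([[np.inf, 0], [0, 1]]))


class TestTuneClassifier:
    def test_single_point_grid(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 10 + [2] * 10)
        grid = [{"sigma": 0.01, "cost": 1}]
        assert tune_classifier(X, y, make_svm, grid, rng=rng) == grid[0]

    def test_separable_data_first_maximizer(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (15, 2)),
                       rng.normal(8, 0.3, (15, 2))])
        y = np.array([1] * 15 + [2] * 15)
        grid = [{"sigma": 0.011, "cost": 1}, {"sigma": 0.021, "cost": 2}]
        best = tune_classifier(X, y, make_svm, grid,
                               rng=np.random.default_rng(1))
        assert best == grid[0]  # both reach accuracy 1.0; tie -> first

    def test_determinism(self, rng):
        X = rng.normal(size=(24, 3))
        y = np.array([1] * 12 + [2] * 12)
        grid = [{"sigma": s, "cost": 1} for s in (0.001, 0.05, 0.2)]
        a = tune_classifier(X, y, make_svm, grid, rng=np.random.default_rng(6))
        b = tune_classifier(X, y, make_svm, grid, rng=np.random.default_rng(6))
        assert a == b

    def test_failing_grid_point_scored_zero(self, rng, caplog):
        X = rng.normal(size=(12, 2))
        y = np.array([1] * 6 + [2] * 6)

        def factory(params):
            if params["bad"]:
                raise RuntimeError("cannot train")
            return make_svm({"sigma": 0.05, "cost": 1})

        with caplog.at_level("WARNING"):
            best = tune_classifier(X, y, factory,
                                   [{"bad": True}, {"bad": False}],
                                   rng=np.random.default_rng(2))
        assert best == {"bad": False}


@pytest.fixture(scope="module")
def nested_result():
    ds, _ = generate(SimSpec(n=40, p=60, n_classes=2, m_info=6,
                             manifold="swiss_roll_arcs", noise_sd=0.1, seed=13))
    config = RunConfig(subset_size=6, pop_size=12, generations=6, bags=3,
                       seed=2, embedding="isomap", k_range=(5, 10),
                       outer_folds=5)
    svm_grid = [{"sigma": 0.011, "cost": 1}, {"sigma": 0.051, "cost": 5}]
    nn_grid = [{"hn1": 10, "hn2": 4}]
    # equal-frequency binning keeps the gene pool large enough on this
    # small fixture for fixed-size subsets (MDL filters it below m)
    return nested_cv_evaluate(ds, config, svm_grid=svm_grid, nn_grid=nn_grid,
                              binning="equalfreq")


class TestNestedCV:
    def test_no_leakage(self, nested_result):
        assert audit_leakage(nested_result)
        for outcome in nested_result.folds:
            assert np.intersect1d(outcome.test_indices,
                                  outcome.train_indices).size == 0

    def test_table_shape_and_metrics_range(self, nested_result):
        table = nested_result.table
        assert len(table) == 5 * 2  # folds x classifiers
        assert set(table["classifier"]) == {"svm", "nn"}
        finite = table.dropna()
        for col in ("accuracy", "macro_auc", "micro_auc"):
            assert ((finite[col] >= 0) & (finite[col] <= 1)).all()

    def test_selection_better_than_chance(self, nested_result):
        finite = nested_result.table.dropna()
        assert finite["micro_auc"].mean() > 0.5

    def test_summary_has_mean_and_std(self, nested_result):
        summary = nested_result.summary()
        assert ("accuracy", "mean") in summary.columns


class TestRankingScore:
    def test_dominant_method_wins(self):
        metric_values = pd.DataFrame(
            {("d1", "auc"): {"A": 0.9, "B": 0.8}}
        )
        sizes = pd.DataFrame({"d1": {"A": 10, "B": 20}})
        scores = ranking_score(metric_values, sizes)
        assert scores["A"] < scores["B"]

    def test_identical_methods_tie_with_average_ranks(self):
        metric_values = pd.DataFrame(
            {("d1", "auc"): {"A": 0.9, "B": 0.9}}
        )
        sizes = pd.DataFrame({"d1": {"A": 10, "B": 10}})
        scores = ranking_score(metric_values, sizes)
        assert scores["A"] == scores["B"] == 1.5 + 1.5

    def test_hand_worked_three_method_table(self):
        """3 methods x 2 datasets x 2 metrics, checked against an explicit
        rank-by-rank hand computation."""
        metric_values = pd.DataFrame(
            {
                ("d1", "m1"): {"A": 0.9, "B": 0.8, "C": 0.7},  # ranks 1,2,3
                ("d1", "m2"): {"A": 0.6, "B": 0.7, "C": 0.7},  # ranks 3,1.5,1.5
                ("d2", "m1"): {"A": 0.5, "B": 0.5, "C": 0.9},  # ranks 2.5,2.5,1
                ("d2", "m2"): {"A": 0.8, "B": 0.6, "C": 0.7},  # ranks 1,3,2
            }
        )
        sizes = pd.DataFrame(
            {"d1": {"A": 5, "B": 8, "C": 2},   # ranks 2,3,1
             "d2": {"A": 9, "B": 4, "C": 6}}   # ranks 3,1,2
        )
        scores = ranking_score(metric_values, sizes)
        assert scores["A"] == pytest.approx(1 + 3 + 2.5 + 1 + 2 + 3)
        assert scores["B"] == pytest.approx(2 + 1.5 + 2.5 + 3 + 3 + 1)
        assert scores["C"] == pytest.approx(3 + 1.5 + 1 + 2 + 1 + 2)

    def test_missing_cell_pairwise_complete(self, caplog):
        metric_values = pd.DataFrame(
            {("d1", "m1"): {"A": 0.9, "B": np.nan, "C": 0.7}}
        )
        sizes = pd.DataFrame({"d1": {"A": 5, "B": 8, "C": 2}})
        with caplog.at_level("WARNING"):
            scores = ranking_score(metric_values, sizes)
        assert scores["A"] == pytest.approx(1 + 2)
        assert scores["B"] == pytest.approx(0 + 3)  # no metric rank available

    def test_single_method_raises(self):
        with pytest.raises(ValueError):
            ranking_score(pd.DataFrame({("d1", "m1"): {"A": 1.0}}),
                          pd.DataFrame({"d1": {"A": 3}}))
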