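"""Nested-CV protocol, metric arithmetic, and Shapley attribution tests."""

import numpy as np
import pytest
from scipy import stats

from tapkin.model_eval import (
    CVConfig,
    SingleClassError,
    compute_metrics,
    nested_cv,
    stratified_kfold,
    summarize_metric,
)
from tapkin.shapley import mean_abs_attribution, sampling_shapley


def _separable(n=60, seed=0):
    """Two well-separated Gaussian classes in 4 dimensions."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n // 2, 4))
    X1 = rng.normal(8.0, 1.0, size=(n // 2, 4))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestStratifiedKFold:
    def test_balanced_labels_split_exactly(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(y, 5, seed=1)
        for f in range(5):
            sel = folds == f
            assert sel.sum() == 20
            assert y[sel].sum() == 10

    def test_partition_property(self, rng):
        y = (rng.random(73) < 0.4).astype(int)
        folds = stratified_kfold(y, 5, seed=2)
        assert set(folds) == set(range(5))
        assert len(folds) == 73

    def test_unbalanced_minority_counts(self):
        """47/53 split over 5 folds: per-fold minority counts in {9, 10}."""
        y = np.array([0] * 47 + [1] * 53)
        folds = stratified_kfold(y, 5, seed=3)
        minority = [int((y[folds == f] == 0).sum()) for f in range(5)]
        assert set(minority) <= {9, 10}
        assert sum(minority) == 47

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([0, 0, 0, 1, 1], 3)


class TestComputeMetrics:
    def test_hand_enumerated_confusion_and_rank_auc(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m["precision"] == pytest.approx(1.0)
        assert m["recall"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["auc"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        m = compute_metrics([1, 0, 1], [1, 0, 1], [0.9, 0.1, 0.8])
        assert all(v == 1.0 for v in m.values())

    def test_score_reversal_antisymmetry(self, rng):
        y = np.array([0, 1] * 10)
        s = rng.random(20)
        auc = compute_metrics(y, y, s)["auc"]
        rev = compute_metrics(y, y, -s)["auc"]
        assert auc + rev == pytest.approx(1.0)

    def test_tied_scores_use_midrank(self):
        m = compute_metrics([1, 0], [1, 0], [0.5, 0.5])
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(SingleClassError):
            compute_metrics([1, 1], [1, 1], [0.9, 0.8])


class TestSummarizeMetric:
    def test_identical_values_zero_width(self):
        s = summarize_metric([0.8, 0.8, 0.8])
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.ci_high - s.ci_low == pytest.approx(0.0, abs=1e-12)
        assert s.mean == pytest.approx(0.8)

    def test_closed_form_with_tabulated_t_quantile(self):
        vals = [0.8, 0.9, 0.85, 0.8, 0.9]
        s = summarize_metric(vals)
        sd = np.std(vals, ddof=1)
        half = stats.t.ppf(0.975, 4) * sd / np.sqrt(5)
        assert s.mean == pytest.approx(0.85)
        assert s.ci_low == pytest.approx(0.85 - half)
        assert s.ci_high == pytest.approx(0.85 + half)
        assert s.ci_low <= s.mean <= s.ci_high

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_metric([0.8])


class TestNestedCV:
    def test_separable_data_scores_perfectly(self):
        X, y = _separable()
        rep = nested_cv(X, y, CVConfig(model_family="LR", seed=0,
                                       compute_importances=False))
        for f in rep.folds:
            assert f.accuracy == 1.0
            assert f.auc == 1.0

    def test_permutation_null_auc_near_half(self):
        """Labels shuffled independently of features: no real signal."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        y = np.array([0, 1] * 40)
        rep = nested_cv(X, y, CVConfig(model_family="LR", seed=1,
                                       compute_importances=False))
        assert 0.25 < rep.summaries["auc"].mean < 0.75

    def test_no_leakage_and_partition(self):
        """Inner-search indices never intersect the outer test fold."""
        X, y = _separable(n=50, seed=2)
        events = []
        rep = nested_cv(
            X, y,
            CVConfig(model_family="DT", seed=2, compute_importances=False),
            audit=lambda **kw: events.append(kw),
        )
        outer = {e["fold"]: e for e in events if e["kind"] == "outer"}
        test_union = np.concatenate([e["test"] for e in outer.values()])
        assert sorted(test_union) == list(range(50))          # disjoint cover
        for e in events:
            if e["kind"] == "inner":
                test = set(outer[e["fold"]]["test"])
                assert not (set(e["train"]) | set(e["val"])) & test
                # inner train/val partition the outer-train subset
                assert (set(e["train"]) | set(e["val"])
                        == set(outer[e["fold"]]["train"]))
        assert len(rep.folds) == 5

    def test_train_auc_probes_overfitting(self, small_cohort):
        from tapkin import build_feature_table
        from tapkin.pipeline import feature_matrix

        X, y, names = feature_matrix(build_feature_table(small_cohort))
        rep = nested_cv(X, y, CVConfig(model_family="RF", seed=3, outer_folds=3,
                                       compute_importances=False),
                        feature_names=names)
        s = rep.summaries
        assert s["train_auc"].mean >= s["auc"].mean - 2 * s["auc"].sd


class TestShapley:
    def test_linear_model_closed_form(self, rng):
        """For a linear score the Shapley value is w_j (x_j - E[z_j])."""
        w = np.array([2.0, -1.0, 0.0, 0.5])
        B = rng.normal(size=(300, 4))
        X = rng.normal(size=(5, 4))
        attr = sampling_shapley(lambda Z: Z @ w, B, X,
                                n_permutations=300, rng=0)
        expect = w * (X - B.mean(axis=0))
        assert np.allclose(attr, expect, atol=0.25)

    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(4)
        n = 120
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 5))
        X[:, 2] += 3.0 * y  # only feature 2 carries the label
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression().fit(X, y)
        attr = sampling_shapley(lambda Z: model.decision_function(Z), X,
                                X[:30], n_permutations=40, rng=1)
        imp = mean_abs_attribution(attr)
        assert np.argmax(imp) == 2
        assert imp[2] > 3 * np.delete(imp, 2).max()

    def test_duplicated_feature_shares_attribution(self):
        """Shapley symmetry: a cloned informative feature splits its credit."""
        rng = np.random.default_rng(5)
        B = rng.normal(size=(400, 3))
        B[:, 1] = B[:, 0]  # feature 1 duplicates feature 0
        X = B[:6]

        def score(Z):
            return Z[:, 0] + Z[:, 1]  # symmetric in the duplicated pair

        attr = sampling_shapley(score, B, X, n_permutations=400, rng=2)
        assert np.allclose(attr[:, 0], attr[:, 1], atol=0.2)
        single = sampling_shapley(lambda Z: 2 * Z[:, 0], B, X,
                                  n_permutations=400, rng=3)
        assert np.allclose(attr[:, 0] + attr[:, 1], single[:, 0], atol=0.35)

    def test_constant_feature_gets_zero(self, rng):
        B = np.hstack([rng.normal(size=(100, 2)), np.ones((100, 1))])
        attr = sampling_shapley(lambda Z: Z[:, 0], B, B[:10],
                                n_permutations=50, rng=4)
        assert np.allclose(attr[:, 2], 0.0)
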