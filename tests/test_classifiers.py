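import numpy as np
import pandas as pd
import pytest

from autoppi import (BinnedNaiveBayes, FitReport, GiniDecisionTree,
                     StandardizedKNN, kfold_cv, learning_curve, load_model,
                     save_model, stratified_split)
from autoppi.classifiers import best_split, gini_impurity


class TestStratifiedSplit:
    def _table(self, n_pos, n_neg):
        return pd.DataFrame({"x": np.arange(n_pos + n_neg, dtype=float),
                             "label": [1] * n_pos + [0] * n_neg})

    def test_seventy_thirty_counts(self):
        train, test = stratified_split(self._table(70, 70), 0.7, seed=0)
        assert train["label"].value_counts().to_dict() == {0: 49, 1: 49}
        assert test["label"].value_counts().to_dict() == {0: 21, 1: 21}

    def test_deterministic_per_seed(self):
        t = self._table(50, 50)
        a1, b1 = stratified_split(t, 0.7, seed=3)
        a2, b2 = stratified_split(t, 0.7, seed=3)
        assert set(a1["x"]) == set(a2["x"]) and set(b1["x"]) == set(b2["x"])

    def test_partition_and_stratification_on_odd_sizes(self):
        t = self._table(401, 596)  # 997 rows
        train, test = stratified_split(t, 0.7, seed=1)
        assert len(train) + len(test) == 997
        assert set(train["x"]).isdisjoint(set(test["x"]))
        for cls, total in ((1, 401), (0, 596)):
            n_train = (train["label"] == cls).sum()
            assert abs(n_train - 0.7 * total) <= 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(self._table(1, 50), 0.7, seed=0)


class TestNaiveBayes:
    def test_laplace_hand_count(self):
        """Positives' bins [1,1,2], negatives' [2,2,2], alpha=1."""
        X = np.array([[1], [1], [2], [2], [2], [2]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = BinnedNaiveBayes(alpha=1.0).fit(X, y)
        # categories {1, 2}; P(bin1|pos) = (2+1)/(3+2) = 3/5, P(bin1|neg) = 1/5
        neg_idx, pos_idx = 0, 1  # classes_ sorted
        assert model.conditional_[0][pos_idx, 0] == pytest.approx(3 / 5)
        assert model.conditional_[0][neg_idx, 0] == pytest.approx(1 / 5)
        # posterior for bin 1: (0.6*0.5)/(0.6*0.5 + 0.2*0.5) = 0.75
        assert model.predict_proba([[1]])[0, 1] == pytest.approx(0.75)

    def test_zero_alpha_allows_zero_conditionals(self):
        X = np.array([[1], [1], [2], [2]])
        y = np.array([1, 1, 0, 0])
        model = BinnedNaiveBayes(alpha=0.0).fit(X, y)
        assert model.conditional_[0][0, 0] == 0.0  # bin 1 never seen in class 0
        assert model.predict_proba([[1]])[0, 1] == 1.0

    def test_label_flip_swaps_class_tables(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(60, 2))
        y = rng.integers(0, 2, size=60)
        a = BinnedNaiveBayes(alpha=1.0).fit(X, y)
        b = BinnedNaiveBayes(alpha=1.0).fit(X, 1 - y)
        for ta, tb in zip(a.conditional_, b.conditional_):
            assert np.allclose(ta, tb[::-1])

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 4, size=(100, 3))
        y = rng.integers(0, 2, size=100)
        model = BinnedNaiveBayes(alpha=1.0).fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_uniform_conditionals_return_prior(self):
        X = np.array([[0], [1], [0], [1], [0], [1]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = BinnedNaiveBayes(alpha=1e9).fit(X, y)  # smoothing flattens everything
        assert np.allclose(model.predict_proba(X)[:, 1], 0.5, atol=1e-6)

    def test_unseen_bin_is_an_error(self):
        model = BinnedNaiveBayes(alpha=1.0).fit(np.array([[0], [1]]), np.array([0, 1]))
        with pytest.raises(ValueError, match="unseen"):
            model.predict_proba(np.array([[7]]))

    def test_agrees_with_sklearn_categorical_nb(self):
        from sklearn.naive_bayes import CategoricalNB
        rng = np.random.default_rng(2)
        # every value 0..max observed per feature so category conventions coincide
        X = np.vstack([rng.permutation(np.repeat(np.arange(4), 25)) for _ in range(3)]).T
        y = rng.integers(0, 2, size=100)
        ours = BinnedNaiveBayes(alpha=1.0).fit(X, y)
        ref = CategoricalNB(alpha=1.0).fit(X, y)
        assert np.allclose(ours.predict_proba(X), ref.predict_proba(X), atol=1e-10)


def _oracle_best_split(X, y, min_leaf):
    """Independent exhaustive search over (feature, midpoint threshold)."""
    def gini(v):
        if v.size == 0:
            return 0.0
        p = v.mean()
        return 2 * p * (1 - p)

    n = len(y)
    parent = gini(y)
    best = None
    for j in range(X.shape[1]):
        for t in np.unique(X[:, j])[:-1]:
            uniq = np.unique(X[:, j])
            mid = (t + uniq[uniq > t][0]) / 2
            mask = X[:, j] <= mid
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            dec = parent - (mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])) / n
            if best is None or dec > best[2] + 1e-12:
                best = (j, mid, dec)
    return best


class TestDecisionTree:
    def test_perfectly_separating_feature_gives_depth_one(self):
        X = np.column_stack([np.r_[np.zeros(20), np.ones(20)], np.zeros(40)])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = GiniDecisionTree(max_depth=5, min_leaf=1).fit(X, y)
        assert model.tree_["feature"] == 0
        assert "feature" not in model.tree_["left"]
        assert (model.predict(X) == y).all()

    def test_pure_input_is_a_single_leaf(self):
        model = GiniDecisionTree().fit(np.random.default_rng(0).normal(size=(30, 2)),
                                       np.ones(30, int))
        assert "feature" not in model.tree_
        assert model.predict_proba(np.zeros((1, 2)))[0, 1] == 1.0

    def test_root_split_matches_exhaustive_oracle(self, random_feature_table):
        X, y = random_feature_table
        model = GiniDecisionTree(max_depth=3, min_leaf=5).fit(X, y)
        j, t, dec = _oracle_best_split(X, y, 5)
        assert model.tree_["feature"] == j
        assert model.tree_["threshold"] == pytest.approx(t)
        assert model.tree_["decrease"] == pytest.approx(dec)

    def test_root_split_agrees_with_sklearn(self, random_feature_table):
        from sklearn.tree import DecisionTreeClassifier
        X, y = random_feature_table
        ours = GiniDecisionTree(max_depth=1, min_leaf=5).fit(X, y)
        ref = DecisionTreeClassifier(max_depth=1, min_samples_leaf=5,
                                     random_state=0).fit(X, y)
        assert ours.tree_["feature"] == ref.tree_.feature[0]
        assert ours.tree_["threshold"] == pytest.approx(ref.tree_.threshold[0], abs=1e-7)

    def test_tie_breaks_lowest_feature_then_threshold(self):
        # duplicated perfect feature: index 0 must win
        x = np.r_[np.zeros(10), np.ones(10)]
        X = np.column_stack([x, x])
        y = x.astype(int)
        split = best_split(X, y, min_leaf=1)
        assert split[0] == 0

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            GiniDecisionTree(max_depth=0).fit(np.zeros((4, 1)), np.array([0, 1, 0, 1]))

    def test_scores_are_leaf_fractions_in_unit_interval(self, random_feature_table):
        X, y = random_feature_table
        proba = GiniDecisionTree(max_depth=4).fit(X, y).predict_proba(X)
        assert ((proba >= 0) & (proba <= 1)).all()


class TestKNN:
    def test_query_on_training_point_with_k1(self):
        X = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        model = StandardizedKNN(k=1).fit(X, y)
        assert model.predict_proba([[10.0]])[0, 1] == 1.0
        assert model.predict_proba([[0.0]])[0, 1] == 0.0

    def test_k_equals_n_returns_global_fraction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 2))
        y = np.r_[np.ones(10, int), np.zeros(15, int)]
        model = StandardizedKNN(k=25).fit(X, y)
        assert np.allclose(model.predict_proba(rng.normal(size=(5, 2)))[:, 1], 10 / 25)

    def test_neighbor_sets_match_brute_force(self, random_feature_table):
        X, y = random_feature_table
        X = X[:100]
        y = y[:100]
        model = StandardizedKNN(k=5).fit(X, y)
        got = model.neighbor_indices(X[:20])
        # independent oracle: full pairwise distances on identically prepared data
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        Z = np.hstack([Z, np.zeros_like(Z)])  # no missing values -> zero indicators
        for q in range(20):
            d = np.sqrt(((Z[q] - Z) ** 2).sum(axis=1))
            expected = np.argsort(d, kind="stable")[:5]
            assert got[q].tolist() == expected.tolist()

    def test_exact_ties_break_by_training_row_order(self):
        X = np.array([[0.0], [1.0], [-1.0], [1.0]])  # rows 1 and 3 equidistant twins
        y = np.array([0, 1, 0, 0])
        model = StandardizedKNN(k=1).fit(X, y)
        assert model.neighbor_indices([[1.0]])[0, 0] == 1

    def test_missing_values_imputed_with_indicator(self):
        X = np.array([[0.0, 1.0], [2.0, np.nan], [4.0, 3.0], [6.0, np.nan]])
        y = np.array([0, 1, 0, 1])
        model = StandardizedKNN(k=1).fit(X, y)
        proba = model.predict_proba(np.array([[2.0, np.nan]]))
        assert proba[0, 1] == 1.0  # nearest is row 1, matching missingness pattern

    def test_even_or_oversized_k_rejected(self):
        X, y = np.zeros((4, 1)), np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            StandardizedKNN(k=2).fit(X, y)
        with pytest.raises(ValueError):
            StandardizedKNN(k=5).fit(X, y)

    def test_agrees_with_sklearn_on_clean_data(self, random_feature_table):
        from sklearn.neighbors import KNeighborsClassifier
        X, y = random_feature_table
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        ours = StandardizedKNN(k=5).fit(X, y)
        ref = KNeighborsClassifier(n_neighbors=5).fit(Z, y)
        assert np.allclose(ours.predict_proba(X), ref.predict_proba(Z))


class TestCrossValidation:
    def _separable(self, n=100):
        X = np.column_stack([np.r_[np.zeros(n // 2), np.ones(n // 2)]])
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        return X, y

    def test_constant_classifier_scores_half_on_balanced_data(self):
        class Majority:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.ones(len(X), dtype=int)

        X, y = self._separable(100)
        mean, sd = kfold_cv(Majority, X, y, k_folds=10, seed=0)
        assert mean == pytest.approx(0.5)

    def test_separable_data_gives_zero_error(self):
        X, y = self._separable(100)
        mean, _ = kfold_cv(lambda: BinnedNaiveBayes(alpha=1.0), X, y, k_folds=10, seed=0)
        assert mean == 0.0

    def test_infeasible_folds_rejected(self):
        X = np.zeros((10, 1))
        y = np.r_[np.ones(3, int), np.zeros(7, int)]
        with pytest.raises(ValueError, match="infeasible"):
            kfold_cv(lambda: BinnedNaiveBayes(), X, y, k_folds=5, seed=0)


class TestLearningCurve:
    def test_full_fraction_matches_kfold_cv(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(120, 2)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        y[rng.choice(120, 20, replace=False)] ^= 1
        make = lambda: BinnedNaiveBayes(alpha=1.0, n_categories=[3, 3])
        points = learning_curve(make, X, y, [0.5, 1.0], seed=7, k_folds=5)
        cv_mean, _ = kfold_cv(make, X, y, k_folds=5, seed=7)
        full = [p for p in points if p["fraction"] == 1.0][0]
        assert full["validation_accuracy"] == pytest.approx(1.0 - cv_mean)

    def test_duplicate_fractions_collapse_and_training_accuracy_is_perfect(self):
        X = np.column_stack([np.r_[np.zeros(50), np.ones(50)]])
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        points = learning_curve(lambda: GiniDecisionTree(max_depth=2, min_leaf=1),
                                X, y, [0.5, 0.5, 1.0], seed=0, k_folds=5)
        assert [p["fraction"] for p in points] == [0.5, 1.0]
        assert all(p["train_accuracy"] == 1.0 for p in points)

    def test_too_small_fraction_skipped_with_warning(self, caplog):
        X = np.zeros((20, 1))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        points = learning_curve(lambda: BinnedNaiveBayes(n_categories=[1]),
                                X, y, [0.1, 1.0], seed=0, k_folds=5)
        assert [p["fraction"] for p in points] == [1.0]
        assert any("skipped" in m for m in caplog.messages)


class TestAcceptanceRule:
    @pytest.mark.parametrize("tr,te,expected", [
        (0.10, 0.10, True),
        (0.15, 0.15, True),    # boundary is inclusive
        (0.151, 0.10, False),
        (0.10, 0.2, False),
    ])
    def test_accept_iff_both_errors_at_or_below_ceiling(self, tr, te, expected):
        report = FitReport("NB", training_error=tr, testing_error=te,
                           cv_mean_error=0.1, cv_sd_error=0.01)
        assert report.accepted is expected


class TestSerialization:
    def test_round_trip_preserves_scores(self, tmp_path, random_feature_table):
        X, y = random_feature_table
        Xb = np.floor(np.clip(X, -2, 2)) + 2  # coarse integer bins
        models = {
            "nb": BinnedNaiveBayes(alpha=1.0).fit(Xb, y),
            "dt": GiniDecisionTree(max_depth=4).fit(X, y),
            "knn": StandardizedKNN(k=5).fit(X, y),
        }
        for name, model in models.items():
            path = tmp_path / f"{name}.json"
            save_model(model, path)
            back = load_model(path)
            Xq = Xb[:30] if name == "nb" else X[:30]
            assert np.allclose(back.predict_proba(Xq), model.predict_proba(Xq))
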