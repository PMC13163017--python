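import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bleatkit.prep import (
    ScalerParams,
    apply_scaler,
    fit_scaler,
    select_features,
    smote_balance,
    stratified_split,
)


class TestStratifiedSplit:
    def test_exact_proportional_allocation(self):
        y = np.repeat(["a", "b", "c"], [60, 20, 20])
        split = stratified_split(y, 0.2, seed=0)
        test_labels = y[split.test]
        assert (test_labels == "a").sum() == 12
        assert (test_labels == "b").sum() == 4
        assert (test_labels == "c").sum() == 4

    def test_twenty_percent_within_one_per_class(self):
        rng = np.random.default_rng(4)
        y = rng.choice(["w", "x", "y", "z"], size=173, p=[0.5, 0.3, 0.15, 0.05])
        split = stratified_split(y, 0.2, seed=1)
        for cls in "wxyz":
            n_c = (y == cls).sum()
            n_test = (y[split.test] == cls).sum()
            assert abs(n_test - 0.2 * n_c) < 1.0

    def test_deterministic(self):
        y = np.repeat(["a", "b"], [30, 20])
        s1 = stratified_split(y, 0.2, seed=5)
        s2 = stratified_split(y, 0.2, seed=5)
        np.testing.assert_array_equal(s1.test, s2.test)

    def test_partition_properties(self):
        y = np.repeat(["a", "b", "c"], [11, 7, 5])
        split = stratified_split(y, 0.25, seed=2)
        assert len(np.intersect1d(split.train, split.test)) == 0
        assert len(split.train) + len(split.test) == len(y)

    def test_singleton_class_error_names_class(self):
        y = np.array(["a", "a", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(y, 0.2, seed=0)

    def test_fraction_bounds(self):
        y = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError):
            stratified_split(y, 1.0, seed=0)


class TestSmote:
    def test_balances_to_majority(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((14, 3))
        y = np.array(["A"] * 10 + ["B"] * 4)
        Xb, yb = smote_balance(X, y, seed=0)
        assert (yb == "A").sum() == 10
        assert (yb == "B").sum() == 10

    def test_synthetic_rows_are_convex_combinations(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (12, 2))
        y = np.array(["A"] * 8 + ["B"] * 4)
        Xb, yb = smote_balance(X, y, seed=1)
        originals = X[y == "B"]
        synthetic = Xb[len(X):]
        assert len(synthetic) == 4
        for s in synthetic:
            # s must sit on a segment between two original class-B rows
            found = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    d = originals[j] - originals[i]
                    denom = float(d @ d)
                    if denom < 1e-18:
                        continue
                    u = float((s - originals[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(originals[i] + u * d - s) < 1e-9:
                        found = True
            assert found

    def test_already_balanced_unchanged(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        y = np.array(["A", "A", "A", "B", "B", "B"])
        Xb, yb = smote_balance(X, y, seed=3)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_small_class_k_fallback(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((13, 2))
        y = np.array(["A"] * 10 + ["B"] * 3)  # k=5 > n_B - 1 = 2
        Xb, yb = smote_balance(X, y, k=5, seed=2)
        assert (yb == "B").sum() == 10

    def test_singleton_class_error(self):
        X = np.zeros((3, 2))
        y = np.array(["A", "A", "B"])
        with pytest.raises(ValueError):
            smote_balance(X, y, seed=0)

    def test_histogram_uniform_property(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 4))
        y = np.repeat(["a", "b", "c"], [17, 9, 4])
        _, yb = smote_balance(X, y, seed=7)
        _, counts = np.unique(yb, return_counts=True)
        assert np.all(counts == 17)


class TestScaler:
    def test_column_1_2_3(self):
        params = fit_scaler(np.array([[1.0], [2.0], [3.0]]))
        z = apply_scaler(params, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert params.sigma[0] == pytest.approx(0.81649658, abs=1e-8)

    def test_constant_column_zeroed(self):
        X = np.column_stack([np.full(5, 7.0), np.arange(5.0)])
        params = fit_scaler(X)
        z = apply_scaler(params, X)
        assert not z[:, 0].any()

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-10, 10, (50, 8))
        z = apply_scaler(fit_scaler(X), X)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_unfit_scaler_error(self):
        with pytest.raises(RuntimeError):
            apply_scaler(ScalerParams(), np.zeros((2, 2)))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_zscore_identity_property(self, values):
        X = np.asarray(values)[:, None]
        z = apply_scaler(fit_scaler(X), X)
        assert np.all(np.isfinite(z))
        if np.std(X) > 1e-9:
            assert abs(z.mean()) < 1e-6


class TestSelectFeatures:
    @pytest.mark.parametrize("seed", range(5))
    def test_informative_features_retained(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        informative = rng.standard_normal((n, 3))
        label = (informative[:, 0] + 2 * informative[:, 1] - informative[:, 2] > 0).astype(int)
        noise = rng.standard_normal((n, 20))
        X = np.hstack([informative, noise])
        selected = select_features(X, label, seed=seed)
        assert {0, 1, 2}.issubset(set(selected.tolist()))

    def test_threshold_above_max_errors(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 5))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError):
            select_features(X, y, threshold=10.0, seed=0)

    def test_selection_is_ordered_subset(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 10))
        y = (X[:, 4] > 0).astype(int)
        selected = select_features(X, y, seed=3)
        assert np.all(np.diff(selected) > 0)
        assert set(selected.tolist()).issubset(range(10))

    def test_single_class_error(self):
        X = np.zeros((10, 3))
        y = np.zeros(10)
        with pytest.raises(ValueError):
            select_features(X, y)
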