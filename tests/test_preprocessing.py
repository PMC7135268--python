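"""Dichotomization, splitting, train-derived scaling, balancing, VIF."""

import numpy as np
import pandas as pd
import pytest

from strokexplain import FEATURES
from strokexplain.preprocessing import (
    apply_preprocess,
    compute_vif,
    dichotomize_mrs,
    fit_preprocess,
    split_train_test,
    subsample_balance,
)


def _frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float), columns=list(FEATURES))


class TestDichotomize:
    @pytest.mark.parametrize(
        "mrs,expected",
        [([0, 1, 2], [0, 0, 0]), ([3, 4, 5, 6], [1, 1, 1, 1]), ([2, 3], [0, 1])],
    )
    def test_good_bad_boundary(self, mrs, expected):
        np.testing.assert_array_equal(dichotomize_mrs(mrs), expected)

    @pytest.mark.parametrize("bad", [[7], [-1], [2, 9]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match="outside"):
            dichotomize_mrs(bad)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_mrs([1.5])


class TestSplit:
    def test_study_size_gives_251_train_63_test(self):
        split = split_train_test(314, seed=0)
        assert len(split.train) == 251 and len(split.test) == 63

    def test_smallest_case(self):
        split = split_train_test(5, seed=0)
        assert len(split.train) == 4 and len(split.test) == 1

    def test_partition_property(self):
        split = split_train_test(101, seed=3)
        union = np.union1d(split.train, split.test)
        np.testing.assert_array_equal(union, np.arange(101))
        assert len(np.intersect1d(split.train, split.test)) == 0

    def test_deterministic_per_seed(self):
        a, b = split_train_test(100, seed=7), split_train_test(100, seed=7)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(4, seed=0)


class TestPreprocessState:
    def test_closed_form_standardization(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0], "nihss": [2.0, 4.0, 6.0]})
        state = fit_preprocess(df)
        Z = apply_preprocess(state, df)
        np.testing.assert_allclose(Z[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_binary_mode_imputation(self):
        df = pd.DataFrame({"sex": [1.0, 1.0, 0.0, np.nan], "age": [1.0, 2.0, 3.0, 4.0]})
        state = fit_preprocess(df)
        assert state.impute_values[0] == 1.0  # mode of the binary column
        Z = apply_preprocess(state, df)
        assert np.isfinite(Z).all()
        # imputed entry equals the standardized mode
        expected = (1.0 - state.means[0]) / state.sds[0]
        assert Z[3, 0] == pytest.approx(expected)

    def test_continuous_mean_imputation(self):
        df = pd.DataFrame({"age": [10.0, np.nan, 20.0], "nihss": [0.0, 1.0, 2.0]})
        state = fit_preprocess(df)
        assert state.impute_values[0] == pytest.approx(15.0)

    def test_train_only_contract(self, rng):
        """Statistics come from train; the transformed test set need not be
        centered, and editing test rows cannot change the fitted state."""
        train = _frame(rng.normal(size=(50, 7)))
        test = _frame(rng.normal(loc=2.0, size=(30, 7)))
        state = fit_preprocess(train)
        Z_test = apply_preprocess(state, test)
        assert abs(Z_test.mean()) > 0.5  # shifted test set stays shifted
        state2 = fit_preprocess(train)  # refit after "modifying" test rows
        np.testing.assert_array_equal(state.means, state2.means)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"age": [1.0, 1.0, 1.0], "nihss": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            fit_preprocess(df)


class TestSubsampleBalance:
    def test_study_class_split_downsamples_to_minority(self, rng):
        y = np.array([1] * 88 + [0] * 226)
        keep = subsample_balance(y, seed=11)
        kept = y[keep]
        assert (kept == 1).sum() == 88 and (kept == 0).sum() == 88
        # every minority row retained
        assert set(np.where(y == 1)[0]) <= set(keep)

    def test_balanced_input_is_noop(self):
        y = np.array([0] * 10 + [1] * 10)
        assert len(subsample_balance(y, seed=0)) == 20

    def test_deterministic_per_seed(self):
        y = np.array([0] * 30 + [1] * 10)
        np.testing.assert_array_equal(
            subsample_balance(y, seed=5), subsample_balance(y, seed=5)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            subsample_balance(np.ones(10), seed=0)


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        X = np.array([[1, 1, 1], [1, -1, 1], [-1, 1, 1], [-1, -1, -1],
                      [1, 1, -1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        np.testing.assert_allclose(compute_vif(X).to_numpy(), 1.0, atol=1e-9)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        vif = compute_vif(X)
        assert np.isinf(vif.iloc[0]) and np.isinf(vif.iloc[1])

    def test_matches_normal_equations_oracle(self, rng):
        """Independently coded least-squares regression of each column on the
        rest reproduces 1/(1-R^2) to 1e-9."""
        base = rng.normal(size=(200, 7))
        X = base + 0.5 * base[:, [0]]  # induce correlation
        vif = compute_vif(X).to_numpy()
        expected = np.empty(7)
        for j in range(7):
            Z = np.hstack([np.ones((200, 1)), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(Z.T @ Z, Z.T @ X[:, j])
            resid = X[:, j] - Z @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            expected[j] = 1 / (1 - r2)
        np.testing.assert_allclose(vif, expected, rtol=0, atol=1e-9)

    def test_permuting_features_permutes_vifs(self, rng):
        X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
        vif = compute_vif(X).to_numpy()
        perm = [2, 0, 4, 1, 3]
        vif_perm = compute_vif(X[:, perm]).to_numpy()
        np.testing.assert_allclose(vif_perm, vif[perm], atol=1e-9)

    def test_vif_at_least_one(self, rng):
        X = rng.normal(size=(60, 4))
        assert (compute_vif(X) >= 1.0 - 1e-12).all()

    def test_missing_values_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, 1.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            compute_vif(X)
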