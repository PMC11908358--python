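"""Logistic-regression phase classification and split evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from twochain.classify import (
    PhaseClassifier,
    classification_accuracy,
    evaluate_splits,
    fit_logistic,
    roc_auc,
    standardize,
    subset_by_divergence_index,
    validate_feature_table,
)
from twochain.errors import UndefinedAUCError


class TestStandardize:
    def test_already_standardised_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 2))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        z, params = standardize(x)
        np.testing.assert_allclose(z, x, atol=1e-12)
        assert not params.degenerate.any()

    def test_constant_feature_flagged_and_zeroed(self):
        x = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        z, params = standardize(x)
        assert params.degenerate[0] and not params.degenerate[1]
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_three_point_population_sd(self):
        z, _ = standardize(np.array([[1.0], [2.0], [3.0]]))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z[:, 0], expected, rtol=1e-12)

    def test_fit_rows_statistics_applied_to_all_rows(self):
        x = np.arange(10.0)[:, None]
        fit_rows = np.zeros(10, dtype=bool)
        fit_rows[:5] = True
        z, params = standardize(x, fit_rows=fit_rows)
        assert params.mean[0] == pytest.approx(2.0)
        assert z[0, 0] == pytest.approx((0 - 2.0) / np.std(np.arange(5.0)))


class TestFitLogistic:
    def test_constant_feature_balanced_classes(self):
        X = np.zeros((20, 1))
        y = np.array([0, 1] * 10)
        fr = fit_logistic(X, y)
        assert abs(fr.coefficients[0]) < 1e-6
        assert abs(fr.intercept) < 1e-6
        np.testing.assert_allclose(fr.predict_proba(X), 0.5, atol=1e-8)

    def test_uninformative_feature_coefficient_near_zero(self):
        rng = np.random.default_rng(1)
        coefs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            x = rng.normal(size=(500, 1))
            y = rng.integers(2, size=500)
            coefs.append(fit_logistic(x, y).coefficients[0])
        # true coefficient is 0; sd of the MLE is ~2/sqrt(n)
        assert abs(np.mean(coefs)) < 3 * 2 / np.sqrt(500) / np.sqrt(10)

    def test_beats_grid_search_on_separable_four_points(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        fr = fit_logistic(X, y)
        assert fr.separation

        def nll(b0, b1):
            eta = b0 + b1 * X[:, 0]
            return np.sum(np.logaddexp(0, eta) - y * eta)

        grid = np.linspace(-12, 12, 100)
        best = min(nll(b0, b1) for b0 in grid for b1 in grid)
        assert fr.negative_log_likelihood <= best + 1e-9

    def test_agrees_with_sklearn_on_nonseparable_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < expit(0.5 + X[:, 0] - 0.7 * X[:, 1])).astype(int)
        ours = fit_logistic(X, y)
        sk = LogisticRegression(C=1e8, tol=1e-12, max_iter=10_000).fit(X, y)
        np.testing.assert_allclose(ours.coefficients, sk.coef_[0], atol=1e-4)
        assert ours.intercept == pytest.approx(sk.intercept_[0], abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((5, 1)), np.ones(5))


class TestRocAuc:
    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_perfect_ordering_gives_one(self):
        assert roc_auc(np.arange(10.0), np.array([0] * 5 + [1] * 5)) == 1.0

    def test_four_point_example(self):
        assert roc_auc(
            np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])
        ) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=100)
        y = rng.integers(2, size=100)
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(3 * s) + 7, y))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc(np.arange(4.0), np.zeros(4))


def table_from(x, y, name="f"):
    return pd.DataFrame(
        {"sequence_id": [f"s{i}" for i in range(len(y))], name: x, "label": y}
    )


class TestEvaluateSplits:
    def test_noise_free_threshold_rule_gives_auc_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=120)
        y = (x > 0.2).astype(int)
        ev = evaluate_splits(table_from(x, y), ["f"], n_splits=40, seed=0)
        assert ev.mean == 1.0

    def test_coin_flip_labels_near_half(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = rng.integers(2, size=200)
        ev = evaluate_splits(table_from(x, y), ["f"], n_splits=100, seed=1)
        assert abs(ev.mean - 0.5) < max(3 * ev.standard_error, 0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = (x + rng.normal(0, 1, 80) > 0).astype(int)
        t = table_from(x, y)
        a = evaluate_splits(t, ["f"], n_splits=30, seed=9)
        b = evaluate_splits(t, ["f"], n_splits=30, seed=9)
        np.testing.assert_array_equal(a.per_split, b.per_split)

    def test_standard_error_definition(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = (x + rng.normal(0, 2, 100) > 0).astype(int)
        ev = evaluate_splits(table_from(x, y), ["f"], n_splits=25, seed=2)
        assert ev.standard_error == pytest.approx(
            np.std(ev.per_split, ddof=1) / np.sqrt(25)
        )

    def test_nested_model_training_deviance_never_increases(self):
        """Adding the split-sum pair in place of the total variance (their
        sum) can only lower the training NLL at the fitted optima."""
        rng = np.random.default_rng(8)
        n = 150
        s_leq = rng.exponential(0.01, n)
        s_gt = rng.exponential(0.004, n)
        var = s_leq + s_gt
        y = (var + rng.normal(0, 0.006, n) < np.median(var)).astype(int)
        df = pd.DataFrame(
            {"contact_variance": var, "S_leq": s_leq, "S_gt": s_gt, "label": y}
        )
        z1, _ = standardize(df[["contact_variance"]].to_numpy())
        z2, _ = standardize(df[["S_leq", "S_gt"]].to_numpy())
        nll1 = fit_logistic(z1, y).negative_log_likelihood
        nll2 = fit_logistic(z2, y).negative_log_likelihood
        assert nll2 <= nll1 + 1e-6


class TestClassificationAccuracy:
    def test_separable_table_reaches_one(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-4, 0.5, 60), rng.normal(4, 0.5, 60)])
        y = np.array([0] * 60 + [1] * 60)
        acc = classification_accuracy(table_from(x, y), ["f"], n_splits=30, seed=0)
        assert acc.mean == 1.0

    def test_constant_feature_predicts_majority(self):
        y = np.array([1] * 70 + [0] * 30)
        acc = classification_accuracy(
            table_from(np.zeros(100), y), ["f"], n_splits=100, seed=3
        )
        assert acc.mean == pytest.approx(0.7, abs=0.03)

    def test_coin_flip_near_half(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = rng.integers(2, size=200)
        acc = classification_accuracy(table_from(x, y), ["f"], n_splits=60, seed=4)
        assert abs(acc.mean - 0.5) < max(3 * acc.standard_error, 0.06)


class TestSubsets:
    def test_top_decile_of_ten_rows_is_single_max(self):
        df = pd.DataFrame(
            {
                "sequence_id": [f"s{i}" for i in range(10)],
                "divergence_index": np.arange(10) / 100.0,
                "label": [0, 1] * 5,
            }
        )
        sub = subset_by_divergence_index(df, fraction=0.1, end="top")
        assert len(sub) == 1
        assert sub.iloc[0]["divergence_index"] == 0.09

    def test_all_tied_takes_first_by_id_with_warning(self):
        df = pd.DataFrame(
            {
                "sequence_id": [f"s{i}" for i in range(10)],
                "divergence_index": np.full(10, 0.5),
            }
        )
        with pytest.warns(RuntimeWarning, match="tie"):
            sub = subset_by_divergence_index(df, fraction=0.3, end="top")
        assert list(sub["sequence_id"]) == ["s0", "s1", "s2"]

    def test_fraction_point_two_takes_two_largest(self):
        df = pd.DataFrame(
            {
                "sequence_id": [f"s{i}" for i in range(10)],
                "divergence_index": (np.arange(10) + 1) / 100.0,
            }
        )
        sub = subset_by_divergence_index(df, fraction=0.2, end="top")
        assert sorted(sub["divergence_index"]) == [0.09, 0.10]
        bottom = subset_by_divergence_index(df, fraction=0.2, end="bottom")
        assert sorted(bottom["divergence_index"]) == [0.01, 0.02]

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            subset_by_divergence_index(pd.DataFrame({"x": [1]}), 0.1)


class TestModelResults:
    def test_fit_and_summary_roundtrip(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        y = (x + rng.normal(0, 0.5, 100) > 0).astype(int)
        model = PhaseClassifier.from_dataframe(
            table_from(x, y, name="contact_variance"), ["contact_variance"]
        )
        res = model.fit()
        assert res.fit.converged
        text = res.summary()
        assert "contact_variance" in text and "AUC" in text
        assert res.training_auc() > 0.8
        preds = res.predict()
        assert set(np.unique(preds)) <= {0, 1}

    def test_validation_catches_missing_and_nonfinite(self):
        df = table_from(np.array([1.0, np.inf, 2.0]), np.array([0, 1, 1]))
        with pytest.raises(ValueError, match="non-finite"):
            validate_feature_table(df, ["f"])
        df2 = table_from(np.arange(3.0), np.array([0.0, np.nan, 1.0]))
        with pytest.raises(ValueError, match="missing labels"):
            validate_feature_table(df2, ["f"])
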