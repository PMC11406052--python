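import numpy as np
import pandas as pd
import pytest

from nanoqrastr import workflow
from nanoqrastr.modeling import (
    SingularDesignError,
    best_subset,
    external_metrics,
    external_metrics_from_predictions,
    fit_mlr,
    golbraikh_tropsha,
    loo_residuals,
    pca_rank_split,
    q2_loo,
    validate_model,
    y_randomization,
)
from conftest import random_regression


class TestFitMLR:
    def test_exact_line_recovered(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = 3.0 + 2.0 * X["x"]
        m = fit_mlr(X, y)
        assert m.intercept == pytest.approx(3.0, abs=1e-10)
        assert m.coef["x"] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(m.predict(X), y)

    def test_orthogonal_response_gives_null_slope(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 0.0, 1.0, 2.0]})
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function of x
        m = fit_mlr(X, y)
        assert m.coef["x"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_solution(self, rng):
        """Cross-check coefficients and SEs against a hand OLS."""
        X, y = random_regression(3, n=30, p=4)
        m = fit_mlr(X, y)
        A = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        sigma2 = resid @ resid / (len(y) - A.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
        assert m.intercept == pytest.approx(beta[0], rel=1e-9)
        assert list(m.coef.values()) == pytest.approx(beta[1:], rel=1e-9)
        assert m.intercept_se == pytest.approx(se[0], rel=1e-9)
        assert list(m.coef_se.values()) == pytest.approx(se[1:], rel=1e-9)

    def test_collinear_columns_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6]})
        X["b"] = 2 * X["a"]
        with pytest.raises(SingularDesignError):
            fit_mlr(X, np.arange(6.0))

    def test_published_table_coefficient_recovery(self):
        """OLS on the printed external table recovers coefficients close to
        the published rounded ones (printed-X rounding bounds agreement)."""
        m = workflow.recover_unrounded_model()
        assert m.intercept == pytest.approx(-2.01, abs=0.06)
        assert m.coef["sum_alpha_sq"] == pytest.approx(0.17, abs=0.01)
        assert m.coef["SE(LK)"] == pytest.approx(5.10, abs=0.02)
        assert m.coef["CVsim(LK)"] == pytest.approx(-10.93, abs=0.06)


class TestQ2LOO:
    def test_noise_free_data_scores_one(self):
        X = pd.DataFrame({"x": np.arange(12.0)})
        q2, press = q2_loo(X, 5 - 0.7 * X["x"])
        assert q2 == pytest.approx(1.0, abs=1e-12)
        assert press == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_refit_and_hat_matrix_routes_agree(self, seed):
        X, y = random_regression(seed, n=20, p=3)
        _, press_hat = q2_loo(X, y, method="hat")
        _, press_refit = q2_loo(X, y, method="refit")
        assert press_refit == pytest.approx(press_hat, rel=1e-8)
        q2_both, _ = q2_loo(X, y, method="both")  # internal assert passes

    def test_pure_noise_scores_below_fit(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.normal(size=12)})
        y = rng.normal(size=12)
        q2, _ = q2_loo(X, y)
        m = fit_mlr(X, y)
        r2 = 1 - ((y - m.predict(X)) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert q2 < r2
        assert q2 < 0.5  # near-null signal cannot cross-validate well

    def test_loo_residuals_match_explicit_refits(self):
        X, y = random_regression(5, n=15, p=2)
        res = loo_residuals(X, y)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            m = fit_mlr(X[mask], y[mask])
            pred = m.predict(X.iloc[[i]])[0]
            assert res[i] == pytest.approx(y[i] - pred, rel=1e-9)


class TestExternalMetrics:
    def test_perfect_predictions(self):
        m = fit_mlr(pd.DataFrame({"x": np.arange(8.0)}),
                    1.0 + 2.0 * np.arange(8.0))
        X_test = pd.DataFrame({"x": [10.0, 11.0]})
        out = external_metrics(m, X_test, 1.0 + 2.0 * X_test["x"])
        assert out["q2_f1"] == pytest.approx(1.0)
        assert out["q2_f2"] == pytest.approx(1.0)
        assert out["rmsep"] == pytest.approx(0.0, abs=1e-10)

    def test_training_mean_prediction_anchors_f1_at_zero(self):
        out = external_metrics_from_predictions(
            [3.0, 5.0, 7.0], [4.0, 4.0, 4.0], y_mean_train=4.0
        )
        assert out["q2_f1"] == pytest.approx(0.0)

    def test_hand_example(self):
        out = external_metrics_from_predictions(
            [1.0, 2.0, 3.0], [1.0, 2.0, 4.0], y_mean_train=1.0
        )
        assert out["q2_f1"] == pytest.approx(0.8)

    def test_zero_test_variance_rejected(self):
        with pytest.raises(ValueError, match="F2"):
            external_metrics_from_predictions(
                [2.0, 2.0], [1.0, 3.0], y_mean_train=0.0
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_f2_never_exceeds_f1(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(10, 3, 9)
        yhat = y + rng.normal(0, 2, 9)
        out = external_metrics_from_predictions(y, yhat, rng.normal(10))
        assert out["q2_f2"] <= out["q2_f1"] + 1e-12


class TestGolbraikhTropsha:
    def test_perfect_agreement_passes_everything(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        gt = golbraikh_tropsha(y, y)
        assert gt["r2"] == pytest.approx(1.0)
        assert gt["r02"] == pytest.approx(1.0)
        assert gt["k"] == pytest.approx(1.0)
        assert gt["all_pass"]

    def test_doubled_predictions_fail_slope(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gt = golbraikh_tropsha(y, 2 * y)
        assert gt["k"] == pytest.approx(0.5)
        assert gt["k_prime"] == pytest.approx(2.0)
        assert not gt["flags"]["slope_ok"]
        assert not gt["all_pass"]

    def test_anticorrelated_predictions_fail(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        gt = golbraikh_tropsha(y, -y + 5)
        assert gt["r2"] == pytest.approx(1.0)  # magnitude alone misleads
        assert not gt["flags"]["positive_correlation"]
        assert not gt["all_pass"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            golbraikh_tropsha([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            golbraikh_tropsha([1.0, 2.0], [1.0, 2.0])


class TestBestSubset:
    def test_single_candidate_when_p_equals_m(self):
        X, y = random_regression(0, n=20, p=3)
        ranked = best_subset(X, y, 3)
        assert len(ranked) == 1
        assert ranked[0]["descriptors"] == ["x0", "x1", "x2"]

    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.standard_normal((40, 10)),
                         columns=[f"d{j:02d}" for j in range(10)])
        y = 4.0 * X["d03"] - 3.0 * X["d07"] + rng.normal(0, 0.3, 40)
        ranked = best_subset(X, y, 2)
        assert ranked[0]["descriptors"] == ["d03", "d07"]

    def test_duplicated_columns_rejected_by_intercorrelation(self):
        X, y = random_regression(2, n=20, p=3)
        X["x_dup"] = X["x0"] * 1.0
        ranked = best_subset(X, y, 2, max_intercorr=0.99)
        assert all(
            not {"x0", "x_dup"} <= set(r["descriptors"]) for r in ranked
        )

    def test_no_survivor_raises_with_cap(self):
        X, y = random_regression(2, n=20, p=2)
        X["x1"] = X["x0"] + 1e-9
        with pytest.raises(ValueError, match="0.9"):
            best_subset(X[["x0", "x1"]], y, 2, max_intercorr=0.90)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_brute_force_reference(self, seed):
        """Independent brute force (sklearn fits, explicit LOO) agrees on
        the winning subset and its Q2."""
        from itertools import combinations
        from sklearn.linear_model import LinearRegression

        X, y = random_regression(seed + 100, n=18, p=6, noise=0.8)
        ranked = best_subset(X, y, 2, max_intercorr=1.01)

        def brute_q2(cols):
            press = 0.0
            for i in range(len(y)):
                mask = np.arange(len(y)) != i
                lr = LinearRegression().fit(X.loc[mask, cols], y[mask])
                press += (y[i] - lr.predict(X.loc[[i], cols])[0]) ** 2
            return 1 - press / ((y - y.mean()) ** 2).sum()

        best_brute = max(
            (tuple(c) for c in combinations(sorted(X.columns), 2)),
            key=lambda c: brute_q2(list(c)),
        )
        assert tuple(ranked[0]["descriptors"]) == best_brute
        assert ranked[0]["q2_loo"] == pytest.approx(
            brute_q2(list(best_brute)), rel=1e-8
        )


class TestYRandomization:
    def test_same_seed_reproduces_report(self):
        X, y = random_regression(9, n=20, p=3)
        a = y_randomization(X, y, n_iter=10, seed=5)
        b = y_randomization(X, y, n_iter=10, seed=5)
        assert a == b

    def test_strong_signal_collapses_under_permutation(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.standard_normal((30, 3)),
                         columns=["a", "b", "c"])
        y = 5 * X["a"] - 4 * X["b"] + rng.normal(0, 0.2, 30)
        m = fit_mlr(X, y)
        r2_orig = 1 - ((y - m.predict(X)) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        res = y_randomization(X, y, n_iter=30, seed=1)
        assert r2_orig > 0.9
        assert res["mean_r2"] < 0.5 and res["mean_r2"] < r2_orig / 2
        assert res["not_chance"]

    def test_null_data_mean_r2_near_expectation(self):
        """Under y independent of X, E[R2] is about p/(n-1)."""
        rng = np.random.default_rng(17)
        n, p = 40, 3
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=list("abc"))
        y = rng.standard_normal(n)
        res = y_randomization(X, y, n_iter=60, seed=3)
        assert res["mean_r2"] == pytest.approx(p / (n - 1), abs=0.06)


class TestPCARankSplit:
    def test_paper_consistent_sizes(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 6)))
        train, test = pca_rank_split(X, test_fraction=1 / 3)
        assert len(train) == 16 and len(test) == 8
        assert set(train) | set(test) == set(X.index)

    def test_univariate_ranks_evenly_spaced(self):
        X = pd.DataFrame({"x": np.arange(12.0)}, index=list("abcdefghijkl"))
        _, test = pca_rank_split(X, test_fraction=1 / 3)
        assert test == ["c", "f", "i", "l"]  # every 3rd in rank order

    def test_row_order_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)),
                         index=[f"c{i}" for i in range(20)])
        t1 = pca_rank_split(X)[1]
        shuffled = X.sample(frac=1, random_state=4)
        t2 = pca_rank_split(shuffled)[1]
        assert sorted(t1) == sorted(t2)

    def test_degenerate_input_rejected(self):
        X = pd.DataFrame({"x": [1.0] * 6})
        with pytest.raises(ValueError):
            pca_rank_split(X)


class TestValidateModel:
    def test_full_battery_on_synthetic_signal(self, linear_dataset):
        ds = linear_dataset
        X, y = ds["X"], ds["y"]
        model, report = validate_model(
            X.iloc[:22], y.iloc[:22], X.iloc[22:], y.iloc[22:],
            n_yrand=10, seed=0,
        )
        assert 0 < report.q2_loo <= report.r2 <= 1
        assert report.r2_adj <= report.r2
        assert report.q2_f2 <= report.q2_f1
        assert report.gt is not None and report.yrand["n_iter"] == 10
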