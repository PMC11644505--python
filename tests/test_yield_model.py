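"""Linear yield model: standardization, OLS with CIs, LOOCV, importance."""

import numpy as np
import pandas as pd
import pytest

from tuberspec.yield_model import (
    DegenerateFeatureError, fit_mlr, importance_vs_correlation_report,
    loocv_evaluate, permutation_importance, standardize,
    standardized_residuals,
)


class TestStandardize:
    def test_simple_column(self):
        Z, _ = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(Z["a"], [-1, 0, 1])

    def test_already_standardized_identity(self, rng):
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        Z, _ = standardize(pd.DataFrame({"a": x}))
        np.testing.assert_allclose(Z["a"], x, atol=1e-12)

    def test_matches_brute_force(self, rng):
        x = rng.normal(3, 7, size=50)
        Z, st = standardize(pd.DataFrame({"a": x}))
        np.testing.assert_allclose(Z["a"], (x - x.mean()) / x.std(ddof=1),
                                   atol=1e-12)
        assert st.center["a"] == pytest.approx(x.mean())

    def test_zero_variance_names_column(self):
        with pytest.raises(DegenerateFeatureError, match="flat"):
            standardize(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestFitMLR:
    def test_exact_linear_single_feature(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x1": x})
        y = pd.Series(3.0 * x, index=X.index)
        fit = fit_mlr(X, y)
        table = fit.coefficients_table().set_index("feature")
        assert table.loc["x1", "coefficient_raw_scale"] == pytest.approx(3.0)
        assert fit.se[0] == pytest.approx(0.0, abs=1e-10)
        assert bool(fit.significant[0])

    def test_matches_normal_equations(self, rng):
        n = 25
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(1.5 * X["a"] - 0.5 * X["b"] + rng.normal(0, 0.3, n),
                      index=X.index)
        fit = fit_mlr(X, y)
        Z, _ = standardize(X)
        M = np.column_stack([np.ones(n), Z.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y.to_numpy())
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-10)

    def test_noise_feature_ci_covers_zero(self, rng):
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 80
            X = pd.DataFrame({
                "signal": r.normal(size=n), "noise": r.normal(size=n),
            })
            y = pd.Series(2.0 * X["signal"] + r.normal(0, 1, n), index=X.index)
            fit = fit_mlr(X, y)
            j = fit.feature_names.index("noise")
            if fit.ci_low[j] <= 0 <= fit.ci_high[j]:
                covered += 1
        assert covered >= int(0.9 * n_seeds) - 1

    def test_rank_deficiency_reported(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = pd.Series(x, index=X.index)
        with pytest.raises(Exception, match="rank|collinear|Collinearity"):
            fit_mlr(X, y)

    def test_prediction_invariant_to_affine_feature_rescaling(self, rng):
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(X["a"] - X["b"] + rng.normal(0, 0.2, n), index=X.index)
        fit1 = fit_mlr(X, y)
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        fit2 = fit_mlr(X2, y)
        np.testing.assert_allclose(fit1.predict(X), fit2.predict(X2),
                                   atol=1e-10)


class TestLoocv:
    def test_noiseless_linear_recovers_exactly(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x})
        y = pd.Series(5.0 + 2.0 * x, index=X.index)
        res = loocv_evaluate(X, y)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_yield_degenerate_r2(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        y = pd.Series(4.0, index=X.index)
        with pytest.warns(UserWarning, match="undefined"):
            res = loocv_evaluate(X, y)
        assert res.r2 is None
        assert res.pct_rmse == pytest.approx(100.0 * res.rmse / 4.0)

    def test_matches_hand_looped_refits(self, rng):
        n = 5
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(rng.normal(size=n) * 2 + 1, index=X.index)
        res = loocv_evaluate(X, y)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xt = X.iloc[mask]
            center, scale = Xt.mean(), Xt.std(ddof=1)
            Zt = (Xt - center) / scale
            M = np.column_stack([np.ones(n - 1), Zt.to_numpy()])
            beta = np.linalg.lstsq(M, y.iloc[mask].to_numpy(), rcond=None)[0]
            z_i = ((X.iloc[i] - center) / scale).to_numpy()
            expected = beta[0] + z_i @ beta[1:]
            assert res.predictions.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_loocv_rmse_not_below_in_sample(self, rng):
        worse = 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            n = 50
            X = pd.DataFrame({"a": r.normal(size=n), "b": r.normal(size=n)})
            y = pd.Series(X["a"] + r.normal(0, 1, n), index=X.index)
            fit = fit_mlr(X, y)
            res = loocv_evaluate(X, y)
            if res.rmse >= fit.in_sample_rmse - 1e-9:
                worse += 1
        assert worse == 8


class TestResidualsAndImportance:
    def test_standardized_residuals_known_values(self):
        preds = pd.Series([2.0, 0.0, -2.0], index=["a", "b", "c"])
        obs = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
        out = standardized_residuals(preds, obs)
        np.testing.assert_allclose(out.to_numpy(), [-1.0, 0.0, 1.0])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictions_warn_and_zero(self):
        preds = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="zero residual"):
            out = standardized_residuals(preds, preds.copy())
        assert (out == 0).all()

    def test_zero_coefficient_feature_zero_importance(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x, "dead": rng.normal(size=n)})
        y = pd.Series(3.0 * x, index=X.index)
        fit = fit_mlr(X, y)
        imp = permutation_importance(fit, X, y, n_rep=10, seed=0)
        imp = imp.set_index("feature")
        assert imp.loc["dead", "importance"] == pytest.approx(0.0, abs=1e-6)

    def test_sole_predictor_has_largest_score(self, rng):
        n = 60
        X = pd.DataFrame({
            "signal": rng.normal(size=n),
            "n1": rng.normal(size=n), "n2": rng.normal(size=n),
        })
        y = pd.Series(4.0 * X["signal"] + rng.normal(0, 0.5, n), index=X.index)
        fit = fit_mlr(X, y)
        imp = permutation_importance(fit, X, y, n_rep=20, seed=1)
        best = imp.sort_values("importance", ascending=False)["feature"].iloc[0]
        assert best == "signal"

    def test_same_seed_identical_scores(self, rng):
        n = 30
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(X["a"] + rng.normal(0, 0.5, n), index=X.index)
        fit = fit_mlr(X, y)
        a = permutation_importance(fit, X, y, n_rep=5, seed=42)
        b = permutation_importance(fit, X, y, n_rep=5, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_nrep_lower_bound(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        y = pd.Series(rng.normal(size=10), index=X.index)
        fit = fit_mlr(X, y)
        with pytest.raises(ValueError, match="n_rep"):
            permutation_importance(fit, X, y, n_rep=1)


class TestComparisonReport:
    def test_single_feature_degenerate(self):
        sel = pd.DataFrame({"feature": ["a"], "r": [0.7], "p": [0.001]})
        imp = pd.DataFrame({"feature": ["a"], "importance": [5.0],
                            "ci_low": [4.0], "ci_high": [6.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            out = importance_vs_correlation_report(sel, imp)
        assert out["abs_r_standardized"].iloc[0] == 0.0

    def test_importance_passthrough_and_sorting(self):
        sel = pd.DataFrame({"feature": ["a", "b", "c"],
                            "r": [0.9, -0.6, 0.3], "p": [0.0, 0.0, 0.01]})
        imp = pd.DataFrame({"feature": ["a", "b", "c"],
                            "importance": [1.0, 3.0, 2.0],
                            "ci_low": [0, 2, 1], "ci_high": [2, 4, 3]})
        out = importance_vs_correlation_report(sel, imp)
        assert list(out["feature"]) == ["b", "c", "a"]
        assert list(out["importance"]) == [3.0, 2.0, 1.0]

    def test_feature_mismatch_rejected(self):
        sel = pd.DataFrame({"feature": ["a"], "r": [0.7], "p": [0.001]})
        imp = pd.DataFrame({"feature": ["b"], "importance": [1.0],
                            "ci_low": [0], "ci_high": [2]})
        with pytest.raises(ValueError, match="differ"):
            importance_vs_correlation_report(sel, imp)
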