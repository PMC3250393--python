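"""Random-forest fusion models: OOB machinery, importance, quantiles, Moran's I."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse import fusion
from canopyfuse.fusion import (
    ModelSpec,
    fit_rf,
    oob_fraction_simulation,
    predict_mean,
    predict_quantiles,
    pseudo_r2,
    residual_correlogram,
    top10_frequency,
    variable_importance,
)


def synthetic_regression(n=120, p=6, noise=0.5, seed=0, signal_col=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
    )
    y = 3.0 * X.iloc[:, signal_col].to_numpy() + rng.normal(0, noise, n)
    return X, y


class TestPseudoR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert pseudo_r2(y, y) == 1.0

    def test_mean_prediction_gives_zero(self):
        y = np.array([0.0, 2.0])
        assert pseudo_r2(y, np.array([1.0, 1.0])) == pytest.approx(0.0)

    def test_hand_evaluated_case(self):
        # MSE = (0 + 1)/2 = 0.5, Var = ((0-1)^2 + (2-1)^2)/2 = 1 -> 0.5
        y = np.array([0.0, 2.0])
        assert pseudo_r2(y, np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_matches_independent_formula_to_1e12(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            y = rng.normal(size=50)
            yhat = rng.normal(size=50)
            # independently coded: population variance, mean squared error
            expected = 1.0 - np.mean((y - yhat) ** 2) / np.mean((y - np.mean(y)) ** 2)
            assert pseudo_r2(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pseudo_r2(np.ones(5), np.ones(5))

    def test_can_be_negative(self):
        y = np.array([0.0, 1.0, 2.0])
        assert pseudo_r2(y, np.array([10.0, -10.0, 10.0])) < 0


class TestFitRF:
    def test_deterministic_for_fixed_seed(self):
        X, y = synthetic_regression()
        a = fit_rf(X, y, ModelSpec(n_trees=50, seed=3))
        b = fit_rf(X, y, ModelSpec(n_trees=50, seed=3))
        np.testing.assert_array_equal(a.oob_prediction, b.oob_prediction)
        assert a.pseudo_r2 == b.pseudo_r2

    def test_every_observation_has_oob_coverage(self):
        X, y = synthetic_regression(n=40)
        fit = fit_rf(X, y, ModelSpec(n_trees=30, seed=1))
        assert fit.oob_mask.any(axis=0).all()

    def test_oob_fraction_near_37_percent_at_369(self):
        X, y = synthetic_regression(n=369, p=4, seed=5)
        fit = fit_rf(X, y, ModelSpec(n_trees=150, seed=2))
        frac = fit.oob_mask.mean(axis=1).mean()
        assert 0.36 <= frac <= 0.38

    def test_signal_model_beats_mean_and_matches_sklearn_oob(self):
        """Cross-check the OOB pseudo-r2 against scikit-learn's independent
        out-of-bag score on the same data and hyperparameters."""
        from sklearn.ensemble import RandomForestRegressor

        X, y = synthetic_regression(n=250, noise=1.0, seed=9)
        fit = fit_rf(X, y, ModelSpec(n_trees=400, seed=4))
        skl = RandomForestRegressor(
            n_estimators=400,
            max_features=fit.spec.mtry(X.shape[1]),
            min_samples_leaf=5,
            oob_score=True,
            random_state=0,
        ).fit(X, y)
        assert fit.pseudo_r2 > 0.5
        assert fit.pseudo_r2 == pytest.approx(skl.oob_score_, abs=0.08)

    def test_missing_values_rejected(self):
        X, y = synthetic_regression(n=30)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_rf(X, y, ModelSpec(n_trees=5))

    def test_too_few_observations_rejected(self):
        X, y = synthetic_regression(n=10)
        with pytest.raises(ValueError, match="20"):
            fit_rf(X, y)

    def test_mtry_rule(self):
        assert ModelSpec().mtry(104) == 34
        assert ModelSpec().mtry(2) == 1


class TestImportance:
    def test_pure_noise_importances_center_at_zero(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = rng.normal(size=100)  # no predictor carries signal
        fit = fit_rf(X, y, ModelSpec(n_trees=150, seed=6))
        imp = variable_importance(fit, seed=1)
        assert abs(imp.mean()) < 0.2 * y.var()

    def test_single_true_driver_ranks_first(self):
        X, y = synthetic_regression(n=150, p=8, noise=0.3, seed=11, signal_col=2)
        fit = fit_rf(X, y, ModelSpec(n_trees=200, seed=7))
        imp = variable_importance(fit, seed=2)
        assert imp.idxmax() == "f2"
        assert imp["f2"] > 5 * imp.drop("f2").abs().max()


class TestTop10:
    @staticmethod
    def _importances(n_models=8, p=20, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"f{j}" for j in range(p)]
        return {
            f"sp{k}": pd.Series(rng.uniform(size=p), index=names)
            for k in range(n_models)
        }

    def test_counting_identity(self):
        imps = self._importances()
        freq = top10_frequency(imps)
        assert freq.sum() == 10 * len(imps)

    def test_single_model_frequencies_binary(self):
        imps = self._importances(n_models=1)
        freq = top10_frequency(imps)
        assert set(freq.unique()) <= {0, 1}

    def test_dominant_predictor_counted_in_every_model(self):
        imps = self._importances()
        for s in imps.values():
            s["f0"] = 100.0
        assert top10_frequency(imps)["f0"] == len(imps)


class TestQuantiles:
    def test_degenerate_single_leaf_returns_raw_quantiles(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = rng.uniform(0, 9, 60)
        # leaves so large each tree is a single node
        fit = fit_rf(X, y, ModelSpec(n_trees=30, seed=2, min_samples_leaf=200))
        # quantile levels chosen off the k/n grid to avoid knife-edge ties
        levels = (0.13, 0.52, 0.87)
        q = predict_quantiles(fit, X.iloc[:3], quantiles=levels)
        # every tree has one leaf holding all training rows, so the weighted
        # distribution is the raw empirical distribution of y
        ys = np.sort(y)
        cum = np.arange(1, 61) / 60.0
        for k, qk in enumerate(levels):
            expected = ys[np.searchsorted(cum, qk)]
            assert q[0, k] == pytest.approx(expected, abs=1e-9)

    def test_quantiles_monotone_everywhere(self):
        X, y = synthetic_regression(n=150, seed=23)
        fit = fit_rf(X, y, ModelSpec(n_trees=100, seed=3))
        q = predict_quantiles(fit, X, quantiles=(0.1, 0.5, 0.9))
        assert (np.diff(q, axis=1) >= -1e-12).all()

    def test_invalid_quantile_rejected(self):
        X, y = synthetic_regression(n=30)
        fit = fit_rf(X, y, ModelSpec(n_trees=10, seed=1))
        with pytest.raises(ValueError):
            predict_quantiles(fit, X.iloc[:2], quantiles=(0.0, 0.5))

    def test_interval_coverage_near_nominal(self):
        """[q10, q90] from the quantile forest covers ~80% of held-out
        responses under a known conditional distribution."""
        rng = np.random.default_rng(31)

        def draw(n):
            X = pd.DataFrame(
                rng.uniform(-2, 2, size=(n, 4)), columns=list("abcd")
            )
            y = X["a"].to_numpy() + rng.normal(0, 1, n)
            return X, y

        X_tr, y_tr = draw(2000)
        X_te, y_te = draw(2000)
        fit = fit_rf(X_tr, y_tr, ModelSpec(n_trees=200, seed=8))
        q = predict_quantiles(fit, X_te, quantiles=(0.1, 0.9))
        coverage = np.mean((y_te >= q[:, 0]) & (y_te <= q[:, 1]))
        assert coverage == pytest.approx(0.80, abs=0.05)


class TestPredictMaps:
    def test_constant_features_give_constant_map(self):
        X, y = synthetic_regression(n=40, seed=2)
        fit = fit_rf(X, y, ModelSpec(n_trees=20, seed=1))
        grid = pd.DataFrame(
            {**{f"f{j}": 0.3 for j in range(6)},
             "x": np.tile([44.4, 133.2], 2),
             "y": np.repeat([44.4, 133.2], 2)},
            index=range(4),
        )
        out = fusion.predict_map(fit, grid, resolution=88.8)
        vals = out.values[np.isfinite(out.values)]
        assert len(np.unique(vals)) == 1

    def test_schema_mismatch_names_missing_columns(self):
        X, y = synthetic_regression(n=40)
        fit = fit_rf(X, y, ModelSpec(n_trees=10, seed=1))
        bad = X.drop(columns=["f3"]).assign(x=1.0, y=1.0)
        with pytest.raises(ValueError, match="f3"):
            fusion.predict_map(fit, bad)

    def test_training_pixels_track_inbag_predictions(self):
        X, y = synthetic_regression(n=60, seed=13)
        fit = fit_rf(X, y, ModelSpec(n_trees=100, seed=5))
        pred = predict_mean(fit, X)
        # in-bag predictions hug the response more tightly than OOB ones
        assert np.mean((pred - y) ** 2) < np.mean((fit.oob_prediction - y) ** 2)


class TestCorrelogram:
    def test_checkerboard_negative_at_short_lag(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        z = ((xs + ys) % 2).ravel() * 2.0 - 1.0
        out = residual_correlogram(z, coords, [0.0, 1.1], n_permutations=49, seed=1)
        assert out["moran_i"].iloc[0] < 0

    def test_smooth_gradient_positive_at_short_lag(self):
        xs, ys = np.meshgrid(np.arange(8.0), np.arange(8.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        z = (xs + ys).ravel().astype(float)
        out = residual_correlogram(z, coords, [0.0, 1.1], n_permutations=99, seed=2)
        assert out["moran_i"].iloc[0] > 0.5
        assert out["p_value"].iloc[0] <= 0.05

    def test_null_p_values_not_extreme(self):
        rng = np.random.default_rng(44)
        coords = rng.uniform(0, 100, size=(40, 2))
        z = rng.normal(size=40)
        out = residual_correlogram(
            z, coords, [0.0, 25.0, 50.0, 75.0], n_permutations=99, seed=3
        )
        assert out["p_value"].dropna().min() > 0.01

    def test_empty_band_reported_missing(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        z = np.array([1.0, -1.0, 0.5])
        out = residual_correlogram(z, coords, [10.0, 20.0], n_permutations=19, seed=4)
        assert np.isnan(out["moran_i"].iloc[0])
        assert out["n_pairs"].iloc[0] == 0

    def test_constant_residuals_error(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            residual_correlogram(np.ones(3), coords, [0.0, 2.0])


class TestOOBSimulation:
    def test_small_n_matches_closed_form(self):
        # P(excluded) = (1 - 1/n)^n
        got = oob_fraction_simulation(n=10, n_resamples=4000, seed=5)
        assert got == pytest.approx((1 - 1 / 10) ** 10, abs=0.01)
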