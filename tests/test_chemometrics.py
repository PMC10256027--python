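"""PLS1 correctness against independent oracles, CV, metrics, LOQ."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mustspec.chemometrics import (
    ChemometricsError,
    compare_methods,
    fit_pls,
    load_model,
    loo_cv,
    loq_ich,
    predict,
    r2_percent,
    rmsep,
    rmsep_percent_of_range,
    save_model,
    simpls_coefficients,
)


def random_problem(seed, n=None, p=None):
    r = np.random.default_rng(seed)
    n = n or int(r.integers(8, 31))
    p = p or int(r.integers(5, 127))
    X = r.normal(size=(n, p))
    beta = r.normal(size=p)
    y = X @ beta + 0.1 * r.normal(size=n)
    return X, y


# ------------------------------------------------------------------- fitting

class TestFitPLS:
    def test_full_rank_full_components_interpolates(self, rng):
        X = rng.normal(size=(12, 4))
        beta = rng.normal(size=4)
        y = X @ beta
        model = fit_pls(X, y, n_components=4)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_first_weight_is_normalized_covariance(self, rng):
        X, y = random_problem(0, n=15, p=8)
        model = fit_pls(X, y, n_components=1)
        Xc = X - X.mean(0)
        w_expected = Xc.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        np.testing.assert_allclose(model.weights[:, 0], w_expected, atol=1e-12)

    def test_predict_on_mean_spectrum_gives_mean_y(self, rng):
        X, y = random_problem(1, n=20, p=10)
        model = fit_pls(X, y, n_components=3)
        assert predict(model, X.mean(0, keepdims=True))[0] == pytest.approx(
            y.mean(), rel=1e-10)

    def test_zero_variance_y_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ChemometricsError):
            fit_pls(X, np.ones(10), 2)

    def test_excessive_components_rejected(self, rng):
        X, y = random_problem(2, n=6, p=4)
        with pytest.raises(ChemometricsError):
            fit_pls(X, y, n_components=6)

    def test_dimension_mismatch_on_predict(self, rng):
        X, y = random_problem(3, n=10, p=6)
        model = fit_pls(X, y, 2)
        with pytest.raises(ChemometricsError):
            predict(model, np.ones((3, 7)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_nipals_matches_simpls(self, seed):
        X, y = random_problem(seed)
        a = min(6, X.shape[0] - 2, X.shape[1])
        model = fit_pls(X, y, a)
        b, intercept = simpls_coefficients(X, y, a)
        scale = max(1.0, float(np.abs(y).max()))
        np.testing.assert_allclose(
            predict(model, X), X @ b + intercept, atol=1e-6 * scale)

    def test_matches_sklearn_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_problem(77, n=20, p=30)
        for a in (1, 3, 6):
            model = fit_pls(X, y, a)
            sk = PLSRegression(n_components=a, scale=False).fit(X, y[:, None])
            np.testing.assert_allclose(
                predict(model, X), sk.predict(X).ravel(), atol=1e-6)

    def test_full_component_limit_is_least_squares(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = fit_pls(X, y, n_components=6)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        ols = Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0] + y.mean()
        np.testing.assert_allclose(predict(model, X), ols, atol=1e-8)

    def test_persistence_round_trip_bit_identical(self, tmp_path, rng):
        X, y = random_problem(5, n=18, p=25)
        model = fit_pls(X, y, 4, analyte="glucose", metadata={"variety": "Riesling"})
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.array_equal(predict(model, X), predict(back, X))
        assert back.metadata["variety"] == "Riesling"


# ---------------------------------------------------------------------- LOO-CV

class TestLooCV:
    def test_matches_brute_force_refit(self, small_design):
        X, ys, groups = small_design
        y = ys["malic_acid"]
        cv = loo_cv(X, y, groups, n_components=6)
        expected = np.empty_like(y)
        for g in np.unique(groups):
            held = groups == g
            m = fit_pls(X[~held], y[~held], 6)
            expected[held] = predict(m, X[held])
        assert np.array_equal(cv.predictions, expected)
        assert cv.rmsep == pytest.approx(rmsep(expected, y))
        assert cv.r2_percent == pytest.approx(r2_percent(expected, y))

    def test_noiseless_latent_model_recovered(self, rng):
        # y from a 2-component linear latent structure, no noise
        T = rng.normal(size=(30, 2))
        P = rng.normal(size=(2, 40))
        X = np.repeat(T, 2, axis=0) @ P   # two replicate rows per sample
        y = np.repeat(T @ np.array([2.0, -1.0]), 2)
        groups = np.repeat(np.arange(30), 2)
        cv = loo_cv(X, y, groups, n_components=2)
        assert cv.rmsep <= 1e-6
        assert cv.r2_percent >= 99.99

    def test_every_spectrum_predicted_once_by_unseen_model(self, small_design):
        X, ys, groups = small_design
        cv = loo_cv(X, ys["fructose"], groups, n_components=6)
        assert cv.n_spectra == len(groups)
        assert cv.n_samples == len(np.unique(groups))
        per_sample = cv.per_sample()
        assert len(per_sample) == cv.n_samples

    def test_too_few_groups_rejected(self, rng):
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)
        with pytest.raises(ChemometricsError, match="3 distinct"):
            loo_cv(X, y, np.array(["a", "a", "a", "b", "b", "b"]), 1)


# --------------------------------------------------------------------- metrics

class TestMetrics:
    @pytest.mark.parametrize(
        "yhat, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([0, 0], [3, 4], np.sqrt(12.5)),
            ([5], [7], 2.0),
        ],
    )
    def test_rmsep_values(self, yhat, y, expected):
        assert rmsep(yhat, y) == pytest.approx(expected, abs=1e-12)

    def test_rmsep_empty_rejected(self):
        with pytest.raises(ChemometricsError):
            rmsep([], [])

    def test_perfect_predictions_give_full_r2(self):
        assert r2_percent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "value, lo, hi, expected",
        [
            (0.43, 6.76, 12.49, 7.504363),  # published Riesling tartaric row
            (0.0, 1.0, 2.0, 0.0),
            (1.0, 4.0, 5.0, 100.0),
        ],
    )
    def test_rmsep_percent_of_range(self, value, lo, hi, expected):
        assert rmsep_percent_of_range(value, lo, hi) == pytest.approx(
            expected, abs=1e-4)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ChemometricsError):
            rmsep_percent_of_range(1.0, 5.0, 5.0)


# ------------------------------------------------------------ method comparison

class TestCompareMethods:
    def make_tables(self, a_vals, b_vals):
        ids = [f"s{i}" for i in range(len(a_vals))]
        a = pd.DataFrame({"sample_id": ids, "glucose_g_l": a_vals})
        b = pd.DataFrame({"sample_id": ids, "glucose_g_l": b_vals})
        return a, b

    def test_identical_methods(self):
        a, b = self.make_tables([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        mc = compare_methods(a, b, "glucose")
        assert mc.slope == pytest.approx(1.0)
        assert mc.intercept == pytest.approx(0.0, abs=1e-12)
        assert mc.r_squared == pytest.approx(1.0)
        assert mc.rmse == pytest.approx(0.0, abs=1e-12)

    def test_rmse_estimates_disagreement_sd(self):
        r = np.random.default_rng(0)
        x = r.uniform(30, 110, 10_000)
        a, b = self.make_tables(x, x + r.normal(0, 4.8, x.size))
        mc = compare_methods(a, b, "glucose")
        assert mc.rmse == pytest.approx(4.8, rel=0.05)

    def test_constant_method_rejected(self):
        a, b = self.make_tables([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ChemometricsError):
            compare_methods(a, b, "glucose")

    def test_too_few_pairs_rejected(self):
        a, b = self.make_tables([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ChemometricsError):
            compare_methods(a, b, "glucose")


# ------------------------------------------------------------------------- LOQ

class TestLoqICH:
    def test_noiseless_line_gives_zero(self):
        c = np.array([1.5, 10.0, 40.0, 90.0])
        curve = loq_ich(c, 3.0 * c + 1.0)
        assert curve.loq == pytest.approx(0.0, abs=1e-10)

    def test_ten_sigma_over_slope(self):
        # residuals orthogonal to [1, c] with exact residual sd 0.2
        c = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to intercept & slope
        e = e / np.sqrt((e**2).sum() / (c.size - 2)) * 0.2
        curve = loq_ich(c, 2.0 * c + e)
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.residual_sd == pytest.approx(0.2, rel=1e-10)
        assert curve.loq == pytest.approx(1.0, rel=1e-10)

    def test_four_stage_dilution_series_shape(self):
        """The reference method's standards design (1.5-90 g/L) fits."""
        from mustspec.synthetic import calibration_series

        series = calibration_series("fructose", seed=4)
        curve = loq_ich(series["concentration_g_l"], series["response"],
                        analyte="fructose")
        assert curve.slope > 0
        assert 0 < curve.loq < 15.0

    def test_nonpositive_slope_rejected(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ChemometricsError, match="slope"):
            loq_ich(c, -2.0 * c)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ChemometricsError):
            loq_ich([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
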