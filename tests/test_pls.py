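"""PLS1 core: oracle equivalence, equivariances, cross-validation."""

import numpy as np
import pytest

from nirquant import (SyntheticConfig, ValidationError, cv_rmsecv, generate,
                      loocv_rmsecv, pls_fit, pls_predict)


def centered_ols_beta(X, y):
    Xc = X - X.mean(axis=0)
    return np.linalg.pinv(Xc) @ (y - y.mean())


class TestFit:
    def test_rank1_single_component_reproduces_y(self, rng):
        y = rng.uniform(1, 5, size=12)
        v = rng.normal(size=30)
        X = np.outer(y, v)
        model = pls_fit(X, y, 1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    @pytest.mark.parametrize("n,p,seed", [(6, 4, 0), (10, 5, 1)])
    def test_saturated_components_match_least_squares(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = pls_fit(X, y, min(n - 1, p))
        np.testing.assert_allclose(model.coefficients,
                                   centered_ols_beta(X, y), atol=1e-6)

    def test_matches_sklearn_nipals_at_intermediate_components(self, rng):
        """Independent cross-check against sklearn's NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 8))
        y = X[:, 1] - 2 * X[:, 5] + rng.normal(0, 0.1, 20)
        for a in (1, 2, 3, 4):
            ours = pls_fit(X, y, a)
            theirs = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.coefficients,
                                       theirs.coef_.ravel(), atol=1e-8)
            np.testing.assert_allclose(ours.predict(X),
                                       theirs.predict(X).ravel(), atol=1e-8)

    def test_y_shift_shifts_predictions(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        base = pls_fit(X, y, 3).predict(X)
        shifted = pls_fit(X, y + 10.0, 3).predict(X)
        np.testing.assert_allclose(shifted, base + 10.0, atol=1e-9)

    def test_y_scaling_scales_predictions(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        base = pls_fit(X, y, 3).predict(X)
        scaled = pls_fit(X, 2.5 * y, 3).predict(X)
        np.testing.assert_allclose(scaled, 2.5 * base, atol=1e-9)

    def test_column_permutation_permutes_coefficients(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        perm = rng.permutation(6)
        base = pls_fit(X, y, 3)
        permuted = pls_fit(X[:, perm], y, 3)
        np.testing.assert_allclose(permuted.coefficients,
                                   base.coefficients[perm], atol=1e-9)

    def test_component_count_validation(self, rng):
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=5)
        with pytest.raises(ValidationError, match="n_components"):
            pls_fit(X, y, 5)

    def test_zero_variance_y_errors(self, rng):
        with pytest.raises(ValidationError, match="zero variance"):
            pls_fit(rng.normal(size=(5, 3)), np.ones(5), 1)

    def test_eighteen_components_supported(self, rng):
        X = rng.normal(size=(30, 40))
        y = rng.normal(size=30)
        model = pls_fit(X, y, 18)
        assert model.n_components == 18
        assert np.all(np.isfinite(model.coefficients))


class TestPredict:
    def test_mean_spectrum_predicts_y_mean(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = pls_fit(X, y, 2)
        assert pls_predict(model, X.mean(axis=0)) == pytest.approx(y.mean())

    def test_channel_mismatch_errors(self, rng):
        model = pls_fit(rng.normal(size=(10, 6)), rng.normal(size=10), 2)
        with pytest.raises(ValidationError, match="channels"):
            model.predict(rng.normal(size=(3, 5)))

    def test_out_of_sample_exact_on_noiseless_data(self):
        cfg = SyntheticConfig(n_samples=40, n_channels=120,
                              baseline_amplitude=0.0, scatter_slope_sd=0.0,
                              scatter_offset_sd=0.0, noise_sd=0.0, seed=21)
        ds = generate(cfg)
        y = ds.references["mannitol"].to_numpy()
        X = ds.spectra.absorbance
        model = pls_fit(X[:30], y[:30], len(cfg.components))
        np.testing.assert_allclose(model.predict(X[30:]), y[30:], atol=1e-6)


class TestCrossValidation:
    def test_constant_response_gives_zero_rmsecv(self):
        X = np.tile([[1.0, 2.0, 3.0]], (3, 1))
        y = np.array([4.0, 4.0, 4.0])
        cv = loocv_rmsecv(X + 1e-9 * np.arange(3)[:, None], y, 1)
        np.testing.assert_allclose(cv.rmsecv_by_components, 0.0, atol=1e-12)

    def test_matches_pseudoinverse_oracle_at_saturated_components(self):
        """LOO RMSECV at full component count equals an explicit
        leave-one-out least-squares recomputation."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.3, 10)
        a = 5   # saturated: PLS == OLS on centered data
        cv = loocv_rmsecv(X, y, a)
        sse = 0.0
        for i in range(10):
            keep = np.arange(10) != i
            beta = centered_ols_beta(X[keep], y[keep])
            pred = y[keep].mean() + (X[i] - X[keep].mean(axis=0)) @ beta
            sse += (pred - y[i]) ** 2
        assert cv.rmsecv_by_components[a - 1] == pytest.approx(
            np.sqrt(sse / 10), abs=1e-8)

    def test_rank_two_data_selects_two_components(self):
        cfg = SyntheticConfig(
            n_samples=30, n_channels=80,
            components=(
                *_two_probe_components(),
            ),
            baseline_amplitude=0.0, scatter_slope_sd=0.0,
            scatter_offset_sd=0.0, noise_sd=0.0, seed=13)
        ds = generate(cfg)
        y = ds.references["probe_a"].to_numpy()
        cv = loocv_rmsecv(ds.spectra.absorbance, y, 5)
        assert cv.optimal_components == 2
        assert cv.rmsecv_by_components[1] < cv.rmsecv_by_components[0]

    def test_invariant_to_sample_ordering(self, rng):
        X = rng.normal(size=(14, 6))
        y = rng.normal(size=14)
        perm = rng.permutation(14)
        a = loocv_rmsecv(X, y, 4).rmsecv_by_components
        b = loocv_rmsecv(X[perm], y[perm], 4).rmsecv_by_components
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_optimal_ties_break_toward_fewer_components(self):
        cv_result = cv_rmsecv(np.eye(6) + 0.01, np.arange(6.0), 3, folds=3)
        curve = cv_result.rmsecv_by_components
        assert cv_result.optimal_components == int(np.argmin(curve)) + 1


def _two_probe_components():
    from nirquant.synthetic import ComponentSpec

    return (
        ComponentSpec("probe_a", (1300.0,), (25.0,), (0.02,), 1.0, 5.0),
        ComponentSpec("probe_b", (2100.0,), (25.0,), (0.02,), 1.0, 5.0),
    )
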