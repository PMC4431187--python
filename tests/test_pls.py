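"""NIPALS PLS1, LOO-PRESS factor selection, evaluation protocol."""
import numpy as np
import pytest

import nirpls as n
from nirpls.pls import _r2, fit_pls, loo_press, predict
from nirpls.simulate import interval_recovery_fixture


def naive_loo_press(x, y, a_max):
    """Refit-from-scratch leave-one-out oracle."""
    nn = len(y)
    press = np.zeros(a_max)
    for i in range(nn):
        tr = np.delete(np.arange(nn), i)
        for a in range(1, a_max + 1):
            model = fit_pls(x[tr], y[tr], a)
            press[a - 1] += (y[i] - predict(model, x[i])) ** 2
    return press


class TestFitPredict:
    def test_univariate_line_recovered_exactly(self):
        x = np.arange(1.0, 7.0)[:, None]
        model = fit_pls(x, 2.0 * x.ravel(), 1)
        assert model.coef[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(predict(model, x), 2.0 * x.ravel(), atol=1e-12)

    def test_noiseless_rank3_mixture_is_exact(self, small_noiseless):
        spectra, y, _ = small_noiseless
        model = fit_pls(spectra.absorbance, y, 3)
        rmsec = np.sqrt(np.mean((y - predict(model, spectra.absorbance)) ** 2))
        assert rmsec < 1e-8

    @pytest.mark.parametrize("a", [1, 2, 4])
    def test_matches_established_pls_implementation(self, a, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        ours = predict(fit_pls(x, y, a), x)
        theirs = PLSRegression(n_components=a, scale=False).fit(x, y).predict(x)
        np.testing.assert_allclose(ours, theirs.ravel(), atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        x = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        model = fit_pls(x, y, 3)
        assert predict(model, x.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)

    def test_batch_predict_equals_rowwise(self, rng):
        x = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        model = fit_pls(x, y, 2)
        batch = predict(model, x)
        rows = np.array([predict(model, row) for row in x])
        np.testing.assert_allclose(batch, rows, atol=1e-12)

    def test_full_mask_equals_unmasked_model_bitwise(self, rng):
        x = rng.standard_normal((20, 12))
        y = rng.standard_normal(20)
        plain = fit_pls(x, y, 3)
        masked = fit_pls(x, y, 3, mask=np.ones(12, dtype=bool))
        np.testing.assert_array_equal(plain.coef, masked.coef)
        np.testing.assert_array_equal(predict(plain, x), predict(masked, x))

    def test_rmsec_nonincreasing_in_factor_count(self, rng):
        x = rng.standard_normal((25, 15))
        y = x @ rng.standard_normal(15) + 0.3 * rng.standard_normal(25)
        rmsecs = [
            np.sqrt(np.mean((y - predict(fit_pls(x, y, a), x)) ** 2))
            for a in range(1, 9)
        ]
        assert np.all(np.diff(rmsecs) <= 1e-12)

    def test_full_rank_factors_reproduce_least_squares(self, rng):
        x = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        model = fit_pls(x, y, 5)
        xc = np.column_stack([np.ones(30), x])
        beta = np.linalg.lstsq(xc, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, x), xc @ beta, atol=1e-8)

    def test_error_cases(self, rng):
        x = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(x, np.ones(10), 2)
        with pytest.raises(ValueError):
            fit_pls(x, y, 5)  # exceeds min(N-1, P)
        rank_deficient = np.outer(rng.standard_normal(10), rng.standard_normal(4))
        with pytest.raises(ValueError, match="factors"):
            fit_pls(rank_deficient, rank_deficient[:, 0], 3)
        with pytest.raises(ValueError, match="grid mismatch"):
            predict(fit_pls(x, y, 2), rng.standard_normal((3, 5)))


class TestLOOPress:
    def test_matches_refit_from_scratch_oracle(self, rng):
        x = rng.standard_normal((18, 12))
        y = x[:, :3] @ rng.standard_normal(3) + 0.2 * rng.standard_normal(18)
        curve = loo_press(x, y, a_max=6)
        np.testing.assert_allclose(curve.press, naive_loo_press(x, y, 6), rtol=1e-9)

    def test_rmsecv_is_definitionally_consistent(self, rng):
        x = rng.standard_normal((15, 10))
        y = rng.standard_normal(15)
        curve = loo_press(x, y, a_max=4)
        assert curve.selected_rmsecv == pytest.approx(
            np.sqrt(curve.press[curve.selected - 1] / 15)
        )

    def test_noiseless_fixture_selects_true_rank(self, small_noiseless):
        spectra, y, _ = small_noiseless
        curve = loo_press(spectra.absorbance, y, a_max=10)
        assert curve.selected == 3
        assert curve.selected_rmsecv < 1e-8

    def test_pure_noise_response_rarely_beats_null_model(self):
        """With an uninformative response, one latent factor should not beat
        the leave-one-out null predictor in most repeats."""
        wins = 0
        for rep in range(50):
            rep_rng = np.random.default_rng(5000 + rep)
            x = rep_rng.standard_normal((20, 10))
            y = rep_rng.standard_normal(20)
            null_press = sum(
                (y[i] - np.delete(y, i).mean()) ** 2 for i in range(20)
            )
            wins += loo_press(x, y, a_max=1).press[0] < null_press
        assert wins <= 25

    def test_a_max_clipped_with_warning(self, rng, caplog):
        x = rng.standard_normal((8, 20))
        y = rng.standard_normal(8)
        with caplog.at_level("WARNING", logger="nirpls.pls"):
            curve = loo_press(x, y, a_max=20)
        assert curve.press.size == 6  # N - 2
        assert "clipping" in caplog.text


class TestEvaluate:
    def test_noiseless_metrics_are_exact(self, small_noiseless):
        spectra, y, _ = small_noiseless
        refs = n.ReferenceSet(analytes=["total"], concentrations=y[:, None])
        split = n.kennard_stone(spectra, 50)
        metrics, model, curve = n.evaluate(spectra, refs, "total", split)
        assert metrics.n_factors == 3
        assert max(metrics.rmsec, metrics.rmsecv, metrics.rmsep) < 1e-8
        assert min(metrics.r2_cal, metrics.r2_cv, metrics.r2_pre) > 0.999999

    def test_constant_prediction_has_nonpositive_r2(self, rng):
        y = rng.standard_normal(20)
        assert _r2(y, np.full(20, y.mean())) == pytest.approx(0.0)
        assert _r2(y, np.full(20, y.mean() + 1.0)) < 0.0

    def test_calibration_fit_is_optimistic_versus_cross_validation(self):
        """R2_cal > R2_cv: the training fit flatters the model relative to
        leave-one-out, across essentially all random datasets."""
        wins = 0
        for seed in range(20):
            spectra, y, _ = interval_recovery_fixture(seed=100 + seed)
            refs = n.ReferenceSet(analytes=["total"], concentrations=y[:, None])
            split = n.kennard_stone(spectra, 50)
            metrics, _, _ = n.evaluate(spectra, refs, "total", split)
            wins += metrics.r2_cal > metrics.r2_cv
        assert wins >= 19

    def test_preprocessing_statistics_frozen_for_prediction(self, small_recovery):
        """An MSC pipeline must evaluate without peeking at prediction data:
        rerunning with an identical calibration set but different prediction
        rows leaves the fitted model unchanged."""
        spectra, y, _ = small_recovery
        refs = n.ReferenceSet(analytes=["total"], concentrations=y[:, None])
        split = n.kennard_stone(spectra, 60)
        _, model_a, _ = n.evaluate(spectra, refs, "total", split, method="MSC")
        perturbed = spectra.absorbance.copy()
        perturbed[split.prediction_sorted()] *= 1.5
        _, model_b, _ = n.evaluate(
            spectra.with_absorbance(perturbed), refs, "total", split, method="MSC"
        )
        np.testing.assert_array_equal(model_a.coef, model_b.coef)
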