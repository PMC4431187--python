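"""Preprocessing operators: SG filtering, SNV, MSC, normalisation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirpls as n
from nirpls.preprocess import Preprocessor


def make_set(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return n.SpectraSet(wavelengths=np.arange(x.shape[1], dtype=float), absorbance=x)


def random_set(rng, n_samples=6, p=64):
    return make_set(rng.standard_normal((n_samples, p)) + 2.0)


class TestSavitzkyGolay:
    def test_quadratic_is_reproduced_exactly(self, rng):
        x = np.arange(101, dtype=float)
        spec = make_set(0.3 * x**2 - 2.0 * x + 5.0)
        out = n.savitzky_golay(spec, window=11, polyorder=2, deriv=0)
        np.testing.assert_allclose(out.absorbance, spec.absorbance, atol=1e-9)

    def test_linear_first_derivative_is_constant_slope(self):
        spec = make_set(0.7 * np.arange(101, dtype=float))
        out = n.savitzky_golay(spec, window=11, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.absorbance, 0.7, atol=1e-10)

    def test_smoothing_matches_per_window_polyfit_oracle(self, rng):
        """Interior points equal an explicit least-squares quadratic fit in
        each centred 11-point window."""
        y = rng.standard_normal(80)
        out = n.savitzky_golay(make_set(y), window=11, polyorder=2).absorbance[0]
        half = 5
        t = np.arange(-half, half + 1, dtype=float)
        for j in range(half, 80 - half):
            coef = np.polynomial.polynomial.polyfit(t, y[j - half : j + half + 1], 2)
            assert out[j] == pytest.approx(coef[0], abs=1e-10)

    def test_invalid_parameters_rejected(self, rng):
        spec = random_set(rng)
        with pytest.raises(ValueError):
            n.savitzky_golay(spec, window=10)
        with pytest.raises(ValueError):
            n.savitzky_golay(spec, window=11, polyorder=11)
        with pytest.raises(ValueError):
            n.savitzky_golay(make_set(np.ones(5)), window=11)


class TestSNV:
    def test_three_point_example(self):
        out = n.snv(make_set([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_rows_have_zero_mean_unit_sd(self, rng):
        out = n.snv(random_set(rng)).absorbance
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        a = n.snv(make_set(x)).absorbance
        b = n.snv(make_set(3.0 + 2.5 * x)).absorbance
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_spectrum_error_names_sample(self, rng):
        spec = n.SpectraSet(
            wavelengths=np.arange(4.0),
            absorbance=np.vstack([rng.standard_normal(4), np.full(4, 2.0)]),
            sample_ids=["good", "flat"],
        )
        with pytest.raises(ValueError, match="flat"):
            n.snv(spec)


class TestMSC:
    def test_reference_row_is_unchanged(self, rng):
        ref = rng.standard_normal(40)
        out, used = n.msc(make_set(ref), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)
        np.testing.assert_array_equal(used, ref)

    def test_affine_distortion_removed_exactly(self, rng):
        ref = rng.standard_normal(40)
        out, _ = n.msc(make_set(0.5 + 2.0 * ref), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        x = rng.standard_normal((5, 30)) + 1.0
        ref = x.mean(axis=0)
        out, _ = n.msc(make_set(x))
        design = np.column_stack([np.ones(30), ref])
        for i in range(5):
            a, b = np.linalg.lstsq(design, x[i], rcond=None)[0]
            np.testing.assert_allclose(
                out.absorbance[i], (x[i] - a) / b, atol=1e-10
            )

    def test_constant_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            n.msc(random_set(rng), reference=np.ones(64))

    def test_prediction_reuses_calibration_reference(self, rng):
        cal, pred = random_set(rng), random_set(rng)
        pp = Preprocessor("msc")
        pp.fit_transform(cal)
        np.testing.assert_array_equal(pp.msc_reference, cal.absorbance.mean(axis=0))
        out = pp.transform(pred)
        expected, _ = n.msc(pred, reference=cal.absorbance.mean(axis=0))
        np.testing.assert_array_equal(out.absorbance, expected.absorbance)

    def test_prediction_before_fit_rejected(self, rng):
        with pytest.raises(ValueError, match="fit_transform"):
            Preprocessor("msc").transform(random_set(rng))


class TestNormalize:
    def test_three_four_five_example(self):
        out = n.normalize(make_set([3.0, 4.0]))
        np.testing.assert_allclose(out.absorbance[0], [0.6, 0.8])

    def test_unit_norm_and_scale_invariance(self, rng):
        spec = random_set(rng)
        out = n.normalize(spec)
        np.testing.assert_allclose(
            np.linalg.norm(out.absorbance, axis=1), 1.0, atol=1e-12
        )
        scaled = n.normalize(spec.with_absorbance(10.0 * spec.absorbance))
        np.testing.assert_allclose(out.absorbance, scaled.absorbance, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            n.normalize(make_set(np.zeros(5)))

    def test_alternative_dialects(self, rng):
        spec = random_set(rng)
        mm = n.normalize(spec, norm="minmax").absorbance
        assert mm.min() == pytest.approx(0.0) and mm.max() == pytest.approx(1.0)
        area = n.normalize(spec, norm="area").absorbance
        np.testing.assert_allclose(np.abs(area).sum(axis=1), 1.0, atol=1e-12)
        with pytest.raises(ValueError):
            n.normalize(spec, norm="bogus")


class TestApplyNamed:
    def test_raw_is_identity(self, rng):
        spec = random_set(rng)
        out, _ = n.apply_named("raw", spec)
        np.testing.assert_array_equal(out.absorbance, spec.absorbance)

    def test_names_are_case_insensitive(self, rng):
        spec = random_set(rng)
        a, _ = n.apply_named("sg11+1d", spec)
        b, _ = n.apply_named("SG11+1D", spec)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_sg11_2d_on_quadratic_is_constant(self):
        spec = make_set(0.25 * np.arange(60, dtype=float) ** 2)
        out, _ = n.apply_named("SG11+2D", spec)
        np.testing.assert_allclose(out.absorbance, 0.5, atol=1e-9)

    def test_window_size_is_honoured(self, rng):
        spec = random_set(rng)
        a, _ = n.apply_named("SG9", spec)
        b, _ = n.apply_named("SG11", spec)
        assert not np.array_equal(a.absorbance, b.absorbance)

    def test_unknown_name_lists_valid_methods(self, rng):
        with pytest.raises(ValueError, match="RAW.*SNV"):
            n.apply_named("osc", random_set(rng))

    def test_prediction_context_requires_fitted_preprocessor(self, rng):
        with pytest.raises(ValueError, match="fitted"):
            n.apply_named("snv", random_set(rng), context="prediction")


matrices = st.integers(0, 2**31 - 1).map(
    lambda s: np.random.default_rng(s).standard_normal((4, 32)) + 1.5
)


class TestOperatorProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(matrices)
    def test_snv_is_idempotent(self, x):
        once = n.snv(make_set(x)).absorbance
        twice = n.snv(make_set(once)).absorbance
        assert np.max(np.abs(twice - once)) < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(matrices)
    def test_normalize_is_idempotent(self, x):
        once = n.normalize(make_set(x)).absorbance
        twice = n.normalize(make_set(once)).absorbance
        assert np.max(np.abs(twice - once)) < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_msc_applied_twice_is_stable(self, seed):
        """On data following the scatter model (rows affine in a common
        shape), re-applying MSC with the corrected-set mean is a no-op."""
        gen = np.random.default_rng(seed)
        shape = gen.standard_normal(32)
        a = gen.uniform(-0.5, 0.5, size=(4, 1))
        b = gen.uniform(0.5, 2.0, size=(4, 1))
        x = a + b * shape + 1e-9 * gen.standard_normal((4, 32))
        once, ref = n.msc(make_set(x))
        twice, _ = n.msc(once, reference=once.absorbance.mean(axis=0))
        delta = np.linalg.norm(twice.absorbance - once.absorbance)
        assert delta < 1e-7 * max(np.linalg.norm(once.absorbance), 1.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(matrices, st.sampled_from(sorted(n.METHOD_NAMES)))
    def test_all_methods_preserve_shape_and_order(self, x, name):
        spec = make_set(x)
        out, _ = n.apply_named(name, spec)
        assert out.absorbance.shape == spec.absorbance.shape
        assert out.sample_ids == spec.sample_ids
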