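"""Pretreatment operators: printed-formula examples and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirquant import (PretreatmentSpec, ValidationError, gap_derivative,
                      msc_fit, msc_transform, sg_smooth, snv)
from conftest import make_spectra


class TestSmoothing:
    def test_uniform_window_center_is_mean(self):
        out = sg_smooth(make_spectra([[1.0, 2.0, 3.0]]), w=1)
        assert out.absorbance[0, 1] == pytest.approx(2.0)

    def test_edges_shrink_window_symmetrically(self):
        out = sg_smooth(make_spectra([[1.0, 2.0, 3.0]]), w=1)
        # at k=0 the symmetric window reduces to the point itself
        np.testing.assert_allclose(out.absorbance[0], [1.0, 2.0, 3.0])

    def test_constant_row_is_unchanged(self):
        out = sg_smooth(make_spectra([[4.2] * 21]), w=5)
        np.testing.assert_allclose(out.absorbance[0], 4.2)

    def test_reduces_white_noise_variance(self, rng):
        x = rng.normal(size=(1, 101))
        out = sg_smooth(make_spectra(x), w=5)
        assert out.absorbance.var() < x.var()

    def test_window_wider_than_spectrum_errors(self):
        with pytest.raises(ValidationError, match="wider"):
            sg_smooth(make_spectra([[1.0, 2.0, 3.0]]), w=2)

    def test_custom_weights_normalized_by_their_sum(self):
        out = sg_smooth(make_spectra([[1.0, 2.0, 3.0]]), w=1,
                        weights=np.array([1.0, 2.0, 1.0]))
        assert out.absorbance[0, 1] == pytest.approx((1 + 4 + 3) / 4)

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 31))
        y = rng.normal(size=(2, 31))
        lhs = sg_smooth(make_spectra(2 * x + 3 * y), w=4).absorbance
        rhs = (2 * sg_smooth(make_spectra(x), w=4).absorbance
               + 3 * sg_smooth(make_spectra(y), w=4).absorbance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestGapDerivative:
    def test_first_derivative_of_unit_ramp_is_two(self):
        # (x[k+1] - x[k-1]) / g with g=1 gives 2 on a unit-slope line
        ramp = np.arange(9.0)
        out = gap_derivative(make_spectra([ramp]), order=1, g=1)
        np.testing.assert_allclose(out.absorbance[0], 2.0)

    def test_conventional_divisor_halves_it(self):
        ramp = np.arange(9.0)
        out = gap_derivative(make_spectra([ramp]), order=1, g=1,
                             conventional=True)
        np.testing.assert_allclose(out.absorbance[0], 1.0)

    def test_second_derivative_annihilates_affine(self):
        affine = 3.0 * np.arange(11.0) + 7.0
        for g in (1, 2, 3):
            out = gap_derivative(make_spectra([affine]), order=2, g=g)
            np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-12)

    def test_second_derivative_of_quadratic(self):
        out = gap_derivative(make_spectra([[0.0, 1.0, 4.0, 9.0, 16.0]]),
                             order=2, g=1)
        np.testing.assert_allclose(out.absorbance[0], [2.0, 2.0, 2.0])

    def test_first_derivative_annihilates_constants(self):
        out = gap_derivative(make_spectra([[5.0] * 11]), order=1, g=3)
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-12)

    def test_edges_trimmed_with_wavelength_axis(self):
        s = make_spectra(np.arange(10.0)[None, :])
        out = gap_derivative(s, order=1, g=2)
        assert out.n_channels == 6
        np.testing.assert_allclose(out.wavelengths_nm, s.wavelengths_nm[2:-2])

    def test_gap_too_large_errors(self):
        with pytest.raises(ValidationError, match="gap"):
            gap_derivative(make_spectra([[1.0, 2.0, 3.0]]), order=1, g=2)


class TestMSC:
    def test_reference_is_columnwise_mean(self):
        ref = msc_fit(make_spectra([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(ref, [1.0, 1.0])

    def test_identity_case(self, rng):
        ref = rng.normal(size=20)
        out = msc_transform(make_spectra(ref[None, :]), ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_exact_affine_inversion(self, rng):
        ref = rng.normal(size=20)
        out = msc_transform(make_spectra((2.0 * ref + 3.0)[None, :]), ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_uses_stored_calibration_reference_not_new_mean(self, rng):
        cal = make_spectra(rng.normal(size=(5, 20)))
        new = make_spectra(rng.normal(size=(3, 20)) + 10.0)
        spec = PretreatmentSpec(method="msc")
        fitted = spec.fit(cal)
        out = fitted.apply(new)
        expected = msc_transform(new, msc_fit(cal))
        np.testing.assert_allclose(out.absorbance, expected.absorbance)

    def test_rank1_reference_is_proportional_to_pure(self, noiseless_rank1):
        ds = noiseless_rank1
        ref = msc_fit(ds.spectra)
        pure = ds.pure_spectra[0]
        cosine = ref @ pure / (np.linalg.norm(ref) * np.linalg.norm(pure))
        assert cosine == pytest.approx(1.0, abs=1e-12)

    def test_equal_composition_rows_coincide_after_msc(self, rng):
        """Rows that differ only by affine scatter map to the same spectrum."""
        base = np.abs(rng.normal(size=30)) + 1.0
        slopes = np.array([0.7, 1.0, 1.4, 2.0])
        offsets = np.array([-0.1, 0.0, 0.2, 0.05])
        x = slopes[:, None] * base + offsets[:, None]
        out = msc_transform(make_spectra(x), x.mean(axis=0))
        for row in out.absorbance:
            np.testing.assert_allclose(row, out.absorbance[0], atol=1e-8)

    def test_constant_reference_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            msc_transform(make_spectra([[1.0, 2.0]]), np.array([3.0, 3.0]))


class TestSNV:
    def test_three_point_row(self):
        out = snv(make_spectra([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_output_mean_zero_sd_one(self, values):
        x = np.asarray(values)
        if np.ptp(x) < 1e-6:   # near-constant rows are numerically degenerate
            return
        out = snv(make_spectra(x[None, :])).absorbance[0]
        assert abs(out.mean()) < 1e-9
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        a = snv(make_spectra(x[None, :])).absorbance
        b = snv(make_spectra((3.5 * x + 2.0)[None, :])).absorbance
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_row_error_names_sample(self):
        s = make_spectra([[1.0, 2.0], [5.0, 5.0]], ids=("ok", "flat"))
        with pytest.raises(ValidationError, match="flat"):
            snv(s)


def test_operators_are_row_independent(rng):
    """Permuting samples permutes outputs identically, for every method."""
    x = np.abs(rng.normal(size=(6, 40))) + 1.0
    perm = rng.permutation(6)
    ids = tuple(f"r{i}" for i in range(6))
    s = make_spectra(x, ids=ids)
    s_perm = make_spectra(x[perm], ids=tuple(ids[i] for i in perm))
    ref = msc_fit(s)
    for fn in (lambda q: sg_smooth(q, 3),
               lambda q: gap_derivative(q, 1, 2),
               lambda q: msc_transform(q, ref),
               snv):
        np.testing.assert_allclose(fn(s).absorbance[perm],
                                   fn(s_perm).absorbance, atol=1e-12)


def test_pretreatment_spec_validation():
    with pytest.raises(ValidationError, match="unknown method"):
        PretreatmentSpec(method="detrend")
    with pytest.raises(ValidationError, match="window"):
        PretreatmentSpec(method="smooth", window_halfwidth=0)


def test_derivative_pipeline_composes_smooth_then_gap(rng):
    x = np.abs(rng.normal(size=(3, 60))) + 1.0
    s = make_spectra(x)
    spec = PretreatmentSpec(method="d2_sg", window_halfwidth=3, gap=2)
    (out,) = spec.fit_apply(s)
    expected = gap_derivative(sg_smooth(s, 3), 2, 2)
    np.testing.assert_allclose(out.absorbance, expected.absorbance)
    assert out.n_channels == 60 - 4
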