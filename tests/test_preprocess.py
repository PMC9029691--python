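import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mozage.preprocess import (
    PreprocessConfig,
    apply_msc,
    apply_pipeline,
    fit_msc_reference,
    savgol_derivative,
    select_bands,
)

from conftest import make_set


class TestConfigInvariants:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=30)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(band_regions=((700, 1000), (900, 1200)))

    def test_deriv_above_polyorder_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_polyorder=2, sg_deriv_order=3)


class TestSelectBands:
    def test_range_and_bands_inclusive(self):
        s = make_set(np.arange(10)[None, :].astype(float), wavelengths=np.arange(1.0, 11.0))
        cfg = PreprocessConfig(range_nm=(1, 10), band_regions=((2, 4), (7, 9)), sg_window=3)
        out = select_bands(s, cfg)
        np.testing.assert_array_equal(out.wavelengths_nm, [2, 3, 4, 7, 8, 9])

    def test_range_only(self):
        s = make_set(np.zeros((1, 10)), wavelengths=np.arange(1.0, 11.0))
        out = select_bands(s, PreprocessConfig(range_nm=(3, 5)))
        np.testing.assert_array_equal(out.wavelengths_nm, [3, 4, 5])

    def test_ugal_lab_band_count_matches_enumeration(self):
        grid = np.arange(350.0, 2501.0)
        s = make_set(np.zeros((1, grid.size)), wavelengths=grid)
        cfg = PreprocessConfig(range_nm=(500, 2400), band_regions=((500, 985), (1015, 2400)))
        out = select_bands(s, cfg)
        # independent brute-force enumeration under the inclusive convention
        expected = sum(
            1
            for w in grid
            if 500 <= w <= 2400 and (500 <= w <= 985 or 1015 <= w <= 2400)
        )
        assert out.n_wavelengths == expected == 1872

    def test_empty_selection_errors(self):
        s = make_set(np.zeros((1, 5)), wavelengths=np.arange(700.0, 705.0))
        with pytest.raises(ValueError, match="every wavelength"):
            select_bands(s, PreprocessConfig(range_nm=(900, 1000)))

    def test_pure_subset_never_reorders(self, rng):
        s = make_set(rng.normal(size=(3, 50)), wavelengths=np.linspace(400, 2400, 50))
        out = select_bands(s, PreprocessConfig(range_nm=(500, 2000)))
        assert np.all(np.diff(out.wavelengths_nm) > 0)
        assert set(out.wavelengths_nm) <= set(s.wavelengths_nm)


class TestMsc:
    def test_reference_of_identical_spectra(self):
        row = np.linspace(0.1, 0.9, 8)
        s = make_set([row, row])
        np.testing.assert_allclose(fit_msc_reference(s), row)

    def test_reference_of_opposite_spectra_is_zero(self):
        row = np.linspace(0.1, 0.9, 8)
        np.testing.assert_allclose(fit_msc_reference(make_set([row, -row])), 0.0, atol=1e-15)

    def test_reference_matches_summation_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        ref = fit_msc_reference(make_set(X))
        oracle = np.array([sum(X[i, j] for i in range(5)) / 5.0 for j in range(4)])
        np.testing.assert_allclose(ref, oracle)

    def test_reference_requires_two_spectra(self):
        with pytest.raises(ValueError):
            fit_msc_reference(make_set(np.ones((1, 5))))

    def test_reference_spectrum_unchanged(self):
        ref = np.linspace(0.2, 0.8, 10)
        out = apply_msc(make_set([ref]), ref)
        np.testing.assert_allclose(out.absorbance_matrix[0], ref, atol=1e-14)

    def test_affine_distortion_recovered(self):
        ref = np.sin(np.linspace(0, 3, 20)) + 1.0
        out = apply_msc(make_set([2.0 * ref + 3.0]), ref)
        np.testing.assert_allclose(out.absorbance_matrix[0], ref, atol=1e-12)

    def test_matches_closed_form_ols_oracle(self, rng):
        ref = rng.normal(size=30)
        x = rng.normal(size=30)
        out = apply_msc(make_set([x]), ref)
        b = np.cov(x, ref, ddof=1)[0, 1] / np.var(ref, ddof=1)
        a = x.mean() - b * ref.mean()
        np.testing.assert_allclose(out.absorbance_matrix[0], (x - a) / b, atol=1e-10)

    def test_idempotent(self, rng):
        ref = np.abs(rng.normal(size=25)) + 0.5
        X = rng.normal(size=(4, 25)) * 0.1 + 2 * ref
        once = apply_msc(make_set(X), ref)
        twice = apply_msc(once, ref)
        np.testing.assert_allclose(
            twice.absorbance_matrix, once.absorbance_matrix, atol=1e-8
        )

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            apply_msc(make_set(np.ones((2, 5))), np.ones(5))

    def test_zero_slope_sample_dropped_with_warning(self):
        ref = np.linspace(0.0, 1.0, 11)
        flat = np.full(11, 0.4)  # orthogonal to the reference: b = 0
        good = 1.5 * ref + 0.1
        with pytest.warns(UserWarning, match="MSC slope"):
            out = apply_msc(make_set([flat, good]), ref)
        assert out.n_samples == 1
        np.testing.assert_allclose(out.absorbance_matrix[0], ref, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-4, 4).filter(lambda v: abs(v) > 1e-3),
    )
    def test_affine_recovery_property(self, a, b):
        ref = np.cos(np.linspace(0, 4, 40)) + 2.0
        out = apply_msc(make_set([a + b * ref]), ref)
        np.testing.assert_allclose(out.absorbance_matrix[0], ref, atol=1e-9)


def _sg_oracle(y, wl, window, polyorder, deriv):
    """Explicit local polynomial fit at each retained point."""
    half = (window - 1) // 2
    out = []
    for i in range(half, y.size - half):
        xs = wl[i - half : i + half + 1] - wl[i]
        coeffs = np.polynomial.polynomial.polyfit(xs, y[i - half : i + half + 1], polyorder)
        out.append(math.factorial(deriv) * coeffs[deriv] if deriv < len(coeffs) else 0.0)
    return np.array(out)


class TestSavgolDerivative:
    def test_constant_gives_zero(self):
        s = make_set(np.full((2, 20), 3.7), wavelengths=np.arange(20.0))
        out = savgol_derivative(s, window=5, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.absorbance_matrix, 0.0, atol=1e-12)
        assert out.n_wavelengths == 16

    def test_linear_ramp_gives_slope(self):
        wl = np.arange(700.0, 740.0, 2.0)  # 2 nm spacing
        m = 0.013
        s = make_set([m * wl], wavelengths=wl)
        out = savgol_derivative(s, window=5, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.absorbance_matrix[0], m, atol=1e-12)

    def test_cubic_matches_analytic_derivative(self):
        wl = np.linspace(1000.0, 1100.0, 51)
        y = 1e-6 * wl**3 - 2e-3 * wl**2 + 0.5 * wl
        dy = 3e-6 * wl**2 - 4e-3 * wl + 0.5
        s = make_set([y], wavelengths=wl)
        out = savgol_derivative(s, window=9, polyorder=3, deriv=1)
        np.testing.assert_allclose(out.absorbance_matrix[0], dy[4:-4], atol=1e-8)

    def test_matches_local_polyfit_oracle(self, rng):
        wl = np.arange(50.0)
        y = rng.normal(size=50)
        s = make_set([y], wavelengths=wl)
        out = savgol_derivative(s, window=7, polyorder=2, deriv=1)
        np.testing.assert_allclose(
            out.absorbance_matrix[0], _sg_oracle(y, wl, 7, 2, 1), atol=1e-9
        )

    def test_banded_grid_processed_per_segment(self, rng):
        wl = np.concatenate([np.arange(500.0, 520.0), np.arange(600.0, 620.0)])
        s = make_set(rng.normal(size=(2, 40)), wavelengths=wl)
        out = savgol_derivative(s, window=5, polyorder=2, deriv=1)
        assert out.n_wavelengths == 40 - 2 * 4  # (window-1) dropped per segment

    def test_irregular_grid_rejected(self, rng):
        wl = np.sort(rng.uniform(0, 100, size=30))
        s = make_set(np.zeros((1, 30)), wavelengths=wl)
        with pytest.raises(ValueError):
            savgol_derivative(s, window=5, polyorder=2, deriv=1)

    def test_window_longer_than_grid_rejected(self):
        s = make_set(np.zeros((1, 5)), wavelengths=np.arange(5.0))
        with pytest.raises(ValueError):
            savgol_derivative(s, window=7, polyorder=2, deriv=1)


class TestPipeline:
    def test_identity_config(self, rng):
        X = rng.normal(size=(3, 20))
        s = make_set(X, wavelengths=np.arange(700.0, 720.0))
        cfg = PreprocessConfig(
            range_nm=(600, 800), apply_msc=False, sg_deriv_order=0, sg_window=5
        )
        out = apply_pipeline(s, cfg, fit=True)
        np.testing.assert_array_equal(out.absorbance_matrix, X)

    def test_fitted_reference_reused(self, rng):
        X = rng.normal(size=(6, 60)) * 0.1 + np.linspace(0.2, 0.8, 60)
        s = make_set(X, wavelengths=np.arange(700.0, 760.0))
        cfg = PreprocessConfig(range_nm=(700, 760), sg_window=7)
        fitted = apply_pipeline(s, cfg, fit=True)
        reused = apply_pipeline(s, cfg, fit=False)
        np.testing.assert_allclose(reused.absorbance_matrix, fitted.absorbance_matrix)

    def test_dimension_bookkeeping_single_segment(self, rng):
        grid = np.arange(350.0, 2501.0)
        X = rng.normal(size=(4, grid.size)) * 0.01 + 0.5
        s = make_set(X, wavelengths=grid)
        cfg = PreprocessConfig(range_nm=(700, 2300))  # defaults: MSC, SG1 window 31
        out = apply_pipeline(s, cfg, fit=True)
        p_selected = np.sum((grid >= 700) & (grid <= 2300))
        assert out.n_wavelengths == p_selected - (31 - 1)
        np.testing.assert_array_equal(cfg.output_grid, out.wavelengths_nm)

    def test_prediction_grid_mismatch_rejected(self, rng):
        grid = np.arange(700.0, 900.0)
        s = make_set(rng.normal(size=(4, 200)) + 1.0, wavelengths=grid)
        cfg = PreprocessConfig(range_nm=(700, 900), sg_window=11)
        apply_pipeline(s, cfg, fit=True)
        other = make_set(rng.normal(size=(2, 150)) + 1.0, wavelengths=grid[:150])
        with pytest.raises(ValueError, match="grid"):
            apply_pipeline(other, cfg, fit=False)

    def test_unfitted_pipeline_rejected_at_predict_time(self, rng):
        s = make_set(rng.normal(size=(3, 50)) + 1.0, wavelengths=np.arange(700.0, 750.0))
        cfg = PreprocessConfig(range_nm=(700, 750), sg_window=7)
        with pytest.raises(ValueError, match="not fitted"):
            apply_pipeline(s, cfg, fit=False)
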