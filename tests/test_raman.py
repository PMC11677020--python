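"""Tests of the Raman preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import welch_t_p
from rsoct.datatypes import SpectrumRecord
from rsoct.raman import (
    PREPROCESS_STAGES,
    PreprocessConfig,
    als_baseline,
    area_normalize,
    calibrate_wavenumber,
    correct_intensity_response,
    emsc_correct,
    preprocess_batch,
    remove_cosmic_spikes,
    select_channels,
    svd_denoise,
    welch_band_select,
)

AXIS = np.linspace(600, 3300, 1024)


def smooth_spectrum():
    return 2.0 + np.exp(-((AXIS - 1400) ** 2) / (2 * 300**2)) + 0.3 * np.sin(AXIS / 400)


class TestSpikeRemoval:
    def test_smooth_spectrum_untouched(self):
        y = smooth_spectrum()
        np.testing.assert_array_equal(remove_cosmic_spikes(y), y)

    def test_constant_spectrum_untouched(self):
        y = np.full(200, 3.7)
        np.testing.assert_array_equal(remove_cosmic_spikes(y), y)

    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_spike_repaired_by_neighbour_interpolation(self, width):
        rng = np.random.default_rng(0)
        y = smooth_spectrum() + rng.normal(0, 0.01, AXIS.size)
        i = 400
        y_spiked = y.copy()
        y_spiked[i : i + width] += 50 * 0.01 * np.array([1.0, 0.9, 0.8][:width])
        out = remove_cosmic_spikes(y_spiked)
        # hand interpolation between the flanking unflagged channels
        for k in range(width):
            frac = (k + 1) / (width + 1)
            expected = y_spiked[i - 1] * (1 - frac) + y_spiked[i + width] * frac
            assert out[i + k] == pytest.approx(expected, abs=1e-12)
        # all other channels bit-identical
        mask = np.ones(AXIS.size, bool)
        mask[i : i + width] = False
        np.testing.assert_array_equal(out[mask], y_spiked[mask])

    def test_all_flagged_is_degenerate(self, monkeypatch):
        import rsoct.raman as rm

        monkeypatch.setattr(rm, "detect_spikes", lambda y, *a, **k: np.ones(y.size, bool))
        with pytest.raises(ValueError):
            rm.remove_cosmic_spikes(np.ones(50))


class TestCalibration:
    def test_identity_line_recovered(self):
        ch = np.arange(0, 1000, 100, dtype=float)
        wn = 600 + 2.6 * ch
        model = calibrate_wavenumber(ch, wn)
        coef = model.pixel_to_wavenumber.coef
        assert coef[0] == pytest.approx(600, abs=1e-8)
        assert coef[1] == pytest.approx(2.6, abs=1e-10)
        np.testing.assert_allclose(coef[2:], 0, atol=1e-10)

    def test_known_degree5_polynomial_recovered(self):
        gen = np.polynomial.Polynomial([600.0, 2.5, 1e-4, -2e-7, 1e-10, -2e-14])
        ch = np.linspace(0, 1000, 12)
        model = calibrate_wavenumber(ch, gen(ch))
        np.testing.assert_allclose(
            model.pixel_to_wavenumber.coef, gen.coef, rtol=1e-6, atol=1e-9
        )
        assert np.max(np.abs(model.residuals)) < 1e-6

    def test_too_few_pairs_rejected(self):
        ch = np.arange(5, dtype=float)
        with pytest.raises(ValueError):
            calibrate_wavenumber(ch, 600 + 2 * ch)

    def test_non_monotone_mapping_rejected(self):
        ch = np.linspace(0, 10, 8)
        wn = np.sin(ch) * 100  # wildly non-monotone target
        with pytest.raises(ValueError):
            calibrate_wavenumber(ch, wn)


class TestResponseCorrection:
    def test_unit_response_is_noop(self):
        y = smooth_spectrum()
        np.testing.assert_array_equal(correct_intensity_response(y, np.ones_like(y)), y)

    def test_division_inverts_multiplication(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(1, 2, 512)
        resp = 0.5 + rng.uniform(0, 1, 512)
        np.testing.assert_allclose(
            correct_intensity_response(true * resp, resp), true, rtol=1e-14
        )

    def test_bad_response_rejected(self):
        y = np.ones(10)
        with pytest.raises(ValueError):
            correct_intensity_response(y, np.ones(9))
        with pytest.raises(ValueError):
            correct_intensity_response(y, np.zeros(10))


class TestSVDDenoise:
    def test_low_rank_matrix_reproduced_exactly(self, rng):
        U = rng.normal(size=(50, 5))
        V = rng.normal(size=(5, 300))
        X = U @ V  # rank 5 <= 30
        np.testing.assert_allclose(svd_denoise(X, 30), X, atol=1e-8 * np.abs(X).max())

    def test_denoising_reduces_error_vs_noise(self, rng):
        U = rng.normal(size=(100, 2))
        V = rng.normal(size=(2, 400))
        signal = U @ V
        noise = rng.normal(0, 0.1, signal.shape)
        den = svd_denoise(signal + noise, 2)
        assert np.linalg.norm(den - signal) < np.linalg.norm(noise)

    def test_rank_clamped_to_batch_size(self, rng):
        X = rng.normal(size=(10, 100))
        np.testing.assert_allclose(svd_denoise(X, 30), X, atol=1e-10)


class TestALSBaseline:
    def test_zero_spectrum(self):
        z, c = als_baseline(np.zeros(500))
        np.testing.assert_allclose(z, 0, atol=1e-12)
        np.testing.assert_allclose(c, 0, atol=1e-12)

    def test_smooth_peakfree_curve_tracked(self):
        x = np.linspace(0, 1, 800)
        y = 2 + 0.5 * x + 0.3 * x**2
        z, c = als_baseline(y)
        # interior: edge effects of the penalty are allowed at the boundary
        inner = slice(50, -50)
        assert np.max(np.abs(c[inner])) < 0.01 * (y.max() - y.min() + 1)

    def test_known_baseline_recovered_under_peaks(self):
        x = AXIS
        base = 3.0 + 1.5 * np.exp(-((x - 1500) ** 2) / (2 * 700**2))
        peaks = np.zeros_like(x)
        for pos in (850, 1450, 2900):
            peaks += 1.0 * np.exp(-((x - pos) ** 2) / (2 * 10**2))
        z, _ = als_baseline(base + peaks)
        off_peak = np.all(
            np.abs(x[:, None] - np.array([850, 1450, 2900])[None]) > 60, axis=1
        )
        off_peak[:30] = off_peak[-30:] = False
        rms = np.sqrt(np.mean((z - base)[off_peak] ** 2))
        assert rms < 0.05 * np.sqrt(np.mean(base[off_peak] ** 2))

    def test_baseline_smoother_than_input(self, rng):
        y = smooth_spectrum() + rng.normal(0, 0.05, AXIS.size)
        z, _ = als_baseline(y)
        energy = lambda v: np.sum(np.diff(v, 2) ** 2)  # noqa: E731
        assert energy(z) <= energy(y)

    def test_nonfinite_rejected(self):
        y = np.ones(100)
        y[3] = np.nan
        with pytest.raises(ValueError):
            als_baseline(y)


class TestEMSC:
    def test_identity_against_reference(self):
        ref = smooth_spectrum()
        corrected, coef = emsc_correct(ref, ref)
        assert coef["b"] == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(coef["poly"], 0, atol=1e-6)
        np.testing.assert_allclose(corrected, ref, atol=1e-6)

    def test_known_mixing_recovered(self):
        rng = np.random.default_rng(2)
        ref = np.abs(rng.normal(1, 0.3, 600)) + np.sin(np.linspace(0, 6, 600))
        interferent = np.cos(np.linspace(0, 3, 600)) ** 2
        y = 2.0 * ref + 0.5 * interferent + 3.0
        corrected, coef = emsc_correct(y, ref, [interferent], poly_order=2)
        assert coef["b"] == pytest.approx(2.0, abs=1e-6)
        assert coef["interferents"][0] == pytest.approx(0.5, abs=1e-6)
        # constant 3 is carried by the Chebyshev order-0 term
        assert coef["poly"][0] == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(corrected, ref, atol=1e-6)

    def test_empty_library_is_msc(self):
        ref = smooth_spectrum()
        y = 1.7 * ref + 0.4
        corrected, coef = emsc_correct(y, ref, (), poly_order=0)
        assert coef["b"] == pytest.approx(1.7, abs=1e-8)
        np.testing.assert_allclose(corrected, ref, atol=1e-7)

    def test_degenerate_scaling_rejected(self):
        ref = smooth_spectrum()
        with pytest.raises(ValueError):
            emsc_correct(np.zeros_like(ref), ref, (), poly_order=0)


class TestAreaNormalize:
    def test_unit_integral(self):
        y = np.abs(smooth_spectrum())
        out = area_normalize(y, AXIS)
        assert np.trapezoid(out, AXIS) == pytest.approx(1.0, abs=1e-10)

    @given(c=st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        y = np.abs(smooth_spectrum())
        np.testing.assert_allclose(
            area_normalize(c * y, AXIS), area_normalize(y, AXIS), rtol=1e-12
        )

    def test_constant_closed_form(self):
        x = np.linspace(0, 10, 101)
        out = area_normalize(np.ones_like(x), x)
        np.testing.assert_allclose(out, 1 / 10.0, rtol=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            area_normalize(np.zeros(100), AXIS[:100])


class TestWelchSelection:
    def test_identical_groups_select_nothing(self, rng):
        X = rng.normal(size=(10, 64))
        sel = welch_band_select(X, X, np.arange(64), alpha=1e-10)
        np.testing.assert_allclose(sel.p_values, 1.0, atol=1e-12)
        assert not sel.mask.any()
        assert sel.regions == []

    def test_shifted_channel_found_and_matches_textbook_formula(self, rng):
        n = 50
        H = rng.normal(size=(n, 30))
        T = rng.normal(size=(n, 30))
        T[:, 7] += 5.0  # 5 pooled-sd shift
        sel = welch_band_select(H, T, np.arange(30), alpha=1e-10)
        assert sel.mask[7]
        assert sel.mask.sum() == 1
        for ch in (0, 7, 15):
            _, p = welch_t_p(H[:, ch], T[:, ch])
            assert sel.p_values[ch] == pytest.approx(p, rel=1e-10)

    def test_mask_monotone_in_alpha(self, rng):
        H = rng.normal(size=(20, 100))
        T = rng.normal(0.5, 1.0, size=(20, 100))
        wn = np.arange(100)
        small = welch_band_select(H, T, wn, alpha=1e-4)
        large = welch_band_select(H, T, wn, alpha=0.05)
        assert np.all(large.mask[small.mask])

    def test_contiguous_regions(self):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(100, 50))
        T = H.copy() + 0.0
        T = rng.normal(size=(100, 50))
        T[:, 10:14] += 4
        T[:, 30] += 4
        sel = welch_band_select(H, T, np.arange(50).astype(float), alpha=1e-10)
        assert (10.0, 13.0) in sel.regions
        assert (30.0, 30.0) in sel.regions

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            welch_band_select(X[:1], X, np.arange(10))


class TestPreprocessBatch:
    def _records(self, Y):
        return [
            SpectrumRecord(AXIS, y, f"su{i % 4}", f"sa{i % 8}", f"r{i}",
                           "tumor" if i % 2 else "healthy")
            for i, y in enumerate(Y)
        ]

    def test_identical_spectra_give_identical_outputs(self, rng):
        y = smooth_spectrum() + 0.5
        recs = []
        base = rng.normal(0, 0.01, AXIS.size)
        for i in range(8):
            recs.append(
                SpectrumRecord(AXIS, y + base, f"su{i%2}", f"sa{i%4}", f"r{i}",
                               "tumor" if i % 2 else "healthy")
            )
        processed, _ = preprocess_batch(recs)
        for r in processed[1:]:
            np.testing.assert_allclose(r.intensities, processed[0].intensities, atol=1e-8)

    def test_unit_area_invariant_and_determinism(self, small_cohort):
        _, spectra, _, _ = small_cohort
        processed, sel = preprocess_batch(spectra)
        for r in processed:
            assert np.trapezoid(r.intensities, r.wavenumbers) == pytest.approx(1.0, abs=1e-10)
        processed2, sel2 = preprocess_batch(spectra)
        for a, b in zip(processed, processed2):
            np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(sel.mask, sel2.mask)

    def test_selected_regions_hit_generator_truth(self):
        """With a strong class effect the Welch regions cover shifted bands."""
        from rsoct.datatypes import CohortSpec
        from rsoct.synthetic import OCTGenParams, generate_cohort

        spec = CohortSpec(
            n_subjects=8, n_healthy_samples=8, n_tumor_samples=8,
            mean_rs_records_per_sample=8.0, mean_oct_records_per_sample=0.2,
            rs_effect_size=6.0, tumor_purity_range=(1.0, 1.0), seed=42,
        )
        spectra, _, truth = generate_cohort(spec, oct_params=OCTGenParams(side=8))
        _, sel = preprocess_batch(spectra)
        assert sel.n_regions >= 1
        # regions sit on (or in the line wings of) truly shifted bands
        hits = 0
        for lo, hi in sel.regions:
            if np.any((truth.shifted_bands() >= lo - 75) & (truth.shifted_bands() <= hi + 75)):
                hits += 1
        assert hits >= 0.8 * len(sel.regions)
        # and most shifted bands are recovered
        covered = sum(
            any(lo - 75 <= b <= hi + 75 for lo, hi in sel.regions)
            for b in truth.shifted_bands()
        )
        assert covered >= 4

    def test_stage_order_is_fixed(self, small_cohort):
        _, spectra, _, _ = small_cohort
        permuted = tuple(reversed(PREPROCESS_STAGES))
        with pytest.raises(ValueError):
            preprocess_batch(spectra, stages=permuted)
        # the canonical order is accepted
        preprocess_batch(spectra[:12], stages=PREPROCESS_STAGES)

    def test_mixed_axes_rejected(self):
        r1 = SpectrumRecord(AXIS, np.ones(1024), "s", "a", "r1", "healthy")
        r2 = SpectrumRecord(AXIS + 1, np.ones(1024), "s", "a", "r2", "tumor")
        with pytest.raises(ValueError):
            preprocess_batch([r1, r2])
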