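import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import double_loop_convolve, tsvd_deconvolve

from perfquant.core import ConcentrationCurve, DynamicSeries, RoiMask, ValidationError
from perfquant.kinetics import (
    FermiFitter,
    FermiParams,
    FitConfig,
    NoContrastError,
    detect_foot,
    enhancement_slope,
    extract_curve,
    extract_pixel_curves,
    fermi_response,
    fit_pixel,
    mbf_map,
    signal_to_concentration,
    trapz_convolve,
)
from perfquant.phantom import gamma_variate_aif, generate_phantom, kety_tissue_curve, PhantomSpec
from perfquant.pipeline import StudyData, aif_in_tissue_units, process_aif, downsample_mask

TIMES = np.arange(60.0)
AIF = gamma_variate_aif((8.0, 2.5, 1.8, 3.5), TIMES)


class TestCurveExtraction:
    def test_constant_frames_give_flat_curve(self):
        series = DynamicSeries(frames=np.full((5, 4, 4), 3.0),
                               times_s=np.arange(5.0))
        mask = RoiMask(np.ones((4, 4)), "myocardium")
        np.testing.assert_array_equal(extract_curve(series, mask), 3.0)

    def test_single_pixel_mask_returns_that_time_course(self, rng):
        frames = rng.uniform(0, 1, (6, 3, 3))
        series = DynamicSeries(frames=frames, times_s=np.arange(6.0))
        mask = np.zeros((3, 3), bool)
        mask[1, 2] = True
        np.testing.assert_array_equal(
            extract_curve(series, RoiMask(mask, "blood_pool")),
            frames[:, 1, 2],
        )

    def test_two_pixel_mean_is_arithmetic_average(self, rng):
        frames = rng.uniform(0, 1, (6, 2, 2))
        series = DynamicSeries(frames=frames, times_s=np.arange(6.0))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[1, 1] = True
        expected = 0.5 * (frames[:, 0, 0] + frames[:, 1, 1])
        np.testing.assert_allclose(
            extract_curve(series, RoiMask(mask, "myocardium")), expected
        )
        curves = extract_pixel_curves(series, RoiMask(mask, "myocardium"))
        assert curves.shape == (2, 6)

    def test_empty_mask_rejected(self):
        series = DynamicSeries(frames=np.ones((5, 2, 2)), times_s=np.arange(5.0))
        with pytest.raises(ValidationError, match="empty"):
            extract_curve(series, RoiMask(np.zeros((2, 2)), "myocardium"))


class TestDetectFoot:
    def test_hand_worked_example(self):
        curve = [10.0, 10.0, 10.0, 10.0, 10.0, 30.0, 80.0]
        # threshold = 10 + max(0, 0.05 * 70) = 13.5; first exceedance at 5
        assert detect_foot(curve, n_baseline_min=4) == 5

    def test_flat_curve_raises_no_contrast(self):
        with pytest.raises(NoContrastError, match="no contrast"):
            detect_foot(np.full(20, 4.0))

    def test_constant_offset_invariance(self, rng):
        base = np.concatenate([np.full(6, 5.0), np.linspace(5, 40, 14)])
        noisy = base + rng.normal(0, 0.01, base.size)
        assert detect_foot(noisy) == detect_foot(noisy + 123.0)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValidationError, match="n_baseline_min"):
            detect_foot(np.ones(5), n_baseline_min=4)


class TestSignalToConcentration:
    def test_prefoot_values_zero_and_clipping(self):
        curve = np.array([5.0, 5.0, 5.0, 5.0, 4.0, 9.0, 15.0])
        conc = signal_to_concentration(curve, np.arange(7.0), foot=4)
        assert np.all(conc.values[:4] == 0.0)  # baseline-subtracted exactly
        assert conc.values[4] == 0.0           # negative excursion clipped
        assert conc.values[6] == pytest.approx(10.0)

    def test_foot_at_zero_rejected(self):
        with pytest.raises(ValidationError, match="foot"):
            signal_to_concentration(np.ones(5), np.arange(5.0), foot=0)


class TestFermiResponse:
    def test_zero_before_delay_and_half_height_at_shoulder(self):
        p = FermiParams(amp=0.1, k_per_s=0.5, w_s=4.0, delay_s=3.0)
        t = np.array([0.0, 2.9, 3.0, 7.0, 100.0])
        r = fermi_response(p, t)
        assert r[0] == r[1] == 0.0
        assert r[3] == pytest.approx(0.05)  # t = delay + w -> amp/2
        assert r[4] == pytest.approx(0.0, abs=1e-8)

    def test_wide_shoulder_limit_is_flat_at_amp(self):
        p = FermiParams(amp=0.2, k_per_s=1.0, w_s=1e6, delay_s=0.0)
        r = fermi_response(p, TIMES)
        np.testing.assert_allclose(r, 0.2, rtol=1e-12)

    @given(st.floats(0.05, 3.0), st.floats(0.0, 10.0), st.floats(0.0, 5.0))
    def test_non_increasing_after_delay(self, k, w, delay):
        p = FermiParams(amp=1.0, k_per_s=k, w_s=w, delay_s=delay)
        r = fermi_response(p, TIMES)
        after = r[TIMES >= delay]
        assert np.all(np.diff(after) <= 1e-12)


class TestConvolution:
    def test_matches_double_loop_exactly_on_five_frame_toys(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 2, 5)
            r = rng.uniform(0, 1, 5)
            dt = float(rng.uniform(0.3, 2.0))
            np.testing.assert_allclose(
                trapz_convolve(a, r, dt), double_loop_convolve(a, r, dt),
                rtol=1e-13, atol=1e-15,
            )

    def test_grid_refinement_changes_mbf_by_under_two_percent(self):
        f, vd = 2.0, 0.15
        for dt in (1.0, 0.5):
            t = np.arange(0.0, 60.0, dt)
            aif = gamma_variate_aif((8.0, 2.5, 1.8, 3.5), t)
            ct = kety_tissue_curve(aif, f, vd)
            _, mbf, _ = fit_pixel(aif, ct, FitConfig())
            if dt == 1.0:
                coarse = mbf
        assert mbf == pytest.approx(coarse, rel=0.02)


class TestFitPixel:
    def test_zero_tissue_gives_zero_flow(self):
        tissue = ConcentrationCurve(np.zeros(60), TIMES)
        params, mbf, diag = fit_pixel(AIF, tissue, FitConfig())
        assert mbf == pytest.approx(0.0, abs=1e-6)
        assert params.amp == pytest.approx(0.0, abs=1e-8)  # at lower bound

    @pytest.mark.parametrize(
        "true",
        [
            FermiParams(amp=0.04, k_per_s=0.3, w_s=4.0, delay_s=2.0),
            FermiParams(amp=0.08, k_per_s=0.8, w_s=2.0, delay_s=0.0),
            FermiParams(amp=0.02, k_per_s=0.15, w_s=8.0, delay_s=1.0),
        ],
    )
    def test_fermi_self_consistency_within_point_one_percent(self, true):
        ct = ConcentrationCurve(
            trapz_convolve(AIF.values, fermi_response(true, TIMES), 1.0), TIMES
        )
        _, mbf, diag = fit_pixel(AIF, ct, FitConfig())
        assert mbf == pytest.approx(true.mbf_ml_min_g, rel=1e-3)
        assert diag["converged"]

    def test_kety_cross_model_within_ten_percent(self):
        ct = kety_tissue_curve(AIF, 2.0, 0.15)
        _, mbf, _ = fit_pixel(AIF, ct, FitConfig())
        assert mbf == pytest.approx(2.0, rel=0.10)

    def test_initial_height_consistent_with_tsvd_oracle(self):
        """Model-independent deconvolution agrees on the response height.

        Checked on a Fermi-shaped response (smooth shoulder, within the
        resolution of truncated-SVD deconvolution; a sharp exponential
        peak would be flattened by any linear regularizer).
        """
        true = FermiParams(amp=0.04, k_per_s=0.3, w_s=4.0, delay_s=0.0)
        ct = ConcentrationCurve(
            trapz_convolve(AIF.values, fermi_response(true, TIMES), 1.0), TIMES
        )
        _, mbf, _ = fit_pixel(AIF, ct, FitConfig())
        h = tsvd_deconvolve(AIF.values, ct.values, 1.0, rel_cutoff=0.02)
        mbf_tsvd = h.max() * 60.0 / 1.05
        assert mbf == pytest.approx(mbf_tsvd, rel=0.15)

    def test_scale_equivariance(self):
        ct = kety_tissue_curve(AIF, 2.0, 0.15)
        _, base, _ = fit_pixel(AIF, ct, FitConfig())
        for c in (0.5, 2.0):
            _, scaled_aif, _ = fit_pixel(AIF.scaled(c), ct, FitConfig())
            assert scaled_aif == pytest.approx(base / c, rel=1e-3)
            _, both, _ = fit_pixel(AIF.scaled(c), ct.scaled(c), FitConfig())
            assert both == pytest.approx(base, rel=1e-6)

    def test_shared_conversion_slope_cancels(self):
        # S = S0 + alpha*C with one alpha for AIF and tissue: MBF unchanged
        ct = kety_tissue_curve(AIF, 2.0, 0.15)
        _, base, _ = fit_pixel(AIF, ct, FitConfig())
        for alpha in (0.5, 2.0):
            _, mbf, _ = fit_pixel(AIF.scaled(alpha), ct.scaled(alpha),
                                  FitConfig())
            assert mbf == pytest.approx(base, rel=1e-6)

    def test_noise_behaviour_unbiased_within_five_percent(self):
        """Mean pixel-wise MBF over a uniform region, SNR 20, >= 500 px."""
        rng = np.random.default_rng(99)
        f = 2.0
        ct = kety_tissue_curve(AIF, f, 0.15)
        sigma_c = 1.0 / (20.0 * enhancement_slope(0.03, 1.0, 4.5))
        Y = ct.values[None, :] + rng.normal(0, sigma_c, (500, 60))
        fitter = FermiFitter(AIF, TIMES, FitConfig())
        flows, _, _ = fitter.fit_many(Y)
        _, noise_free, _ = fitter.fit(ct.values)
        assert flows.mean() == pytest.approx(noise_free, rel=0.05)


def corrected_series_and_aif(study):
    """Baseline-normalized series plus the AIF on the tissue scale."""
    from perfquant.scic import run_scic

    result = run_scic("none", study.perfusion, study.pd,
                      study.masks["myocardium"], study.masks["body"])
    aif = aif_in_tissue_units(
        process_aif(study.aif, downsample_mask(study.masks["blood_pool"], 2),
                    study.signal),
        study.signal,
    )
    return result.series, aif


class TestMbfMap:
    def test_uniform_phantom_map_cov_below_one_percent(self, clean_study):
        series, aif = corrected_series_and_aif(clean_study)
        m = mbf_map(series, aif, clean_study.masks["myocardium"], FitConfig())
        vals = m.converged_values
        assert 100.0 * vals.std(ddof=1) / vals.mean() < 1.0

    def test_two_territory_phantom_ordered_and_within_ten_percent(self):
        spec = PhantomSpec.scaled_default(
            seed=9, grid=48, snr=None,
            coil_gains=[((0.0, 24.0), 0.0, 24.0)],
            territory_mbf={"LAD": 1.0, "LCX": 2.0, "RCA": 2.0},
        )
        study = StudyData.from_phantom(*generate_phantom(spec))
        series, aif = corrected_series_and_aif(study)
        m = mbf_map(series, aif, study.masks["myocardium"], FitConfig())
        lab = study.truth.segment_labels.labels
        lad = m.mbf[(lab == 1) | (lab == 6)].mean()
        rest = m.mbf[(lab > 1) & (lab < 6)].mean()
        assert lad < rest
        assert lad == pytest.approx(1.0, rel=0.10)
        assert rest == pytest.approx(2.0, rel=0.10)

    def test_map_is_deterministic(self, clean_study):
        series, aif = corrected_series_and_aif(clean_study)
        a = mbf_map(series, aif, clean_study.masks["myocardium"], FitConfig())
        b = mbf_map(series, aif, clean_study.masks["myocardium"], FitConfig())
        np.testing.assert_array_equal(
            np.nan_to_num(a.mbf), np.nan_to_num(b.mbf)
        )
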