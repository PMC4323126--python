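import numpy as np
import pytest

from conftest import uniform_signal
from oracles import band_mask_loop

from perfquant.core import BiasField, DynamicSeries, RoiMask, ValidationError
from perfquant.phantom import (
    PhantomSpec,
    _geometry,
    _rician,
    generate_phantom,
)
from perfquant.regional_stats import cov_si
from perfquant.scic import (
    ScicMode,
    apply_scic,
    baseline_normalize,
    build_body_mask,
    fit_bias_surface,
    run_scic,
)


def annulus_masks(grid=48):
    spec = PhantomSpec.scaled_default(seed=0, grid=grid)
    geo = _geometry(spec)
    return (RoiMask(geo["myocardium"], "myocardium"),
            RoiMask(geo["body_outline"], "body"))


class TestBuildBodyMask:
    def test_uniform_image_keeps_outline_minus_myocardium(self):
        myo, outline = annulus_masks()
        ref = np.full(myo.mask.shape, 7.0)
        body = build_body_mask(ref, myo, outline, 0.5, 2.0)
        np.testing.assert_array_equal(body.mask, outline.mask & ~myo.mask)

    def test_bright_patch_excluded(self):
        myo, outline = annulus_masks()
        ref = np.full(myo.mask.shape, 7.0)
        ref[:6] = 5.0 * 7.0
        body = build_body_mask(ref, myo, outline, 0.5, 2.0)
        assert not body.mask[:6].any()

    def test_band_matches_pixel_loop_oracle_with_lung_like_region(self):
        myo, outline = annulus_masks()
        rng = np.random.default_rng(3)
        ref = rng.uniform(4.0, 9.0, myo.mask.shape)
        ref[30:40, 5:15] = 0.1 * np.median(ref[myo.mask])  # lung-like
        body = build_body_mask(ref, myo, outline, 0.5, 2.0)
        expected = band_mask_loop(ref, myo.mask, outline.mask, 0.5, 2.0)
        np.testing.assert_array_equal(body.mask, expected)
        assert not body.mask[30:40, 5:15].any()

    def test_bad_fractions_rejected(self):
        myo, outline = annulus_masks()
        with pytest.raises(ValidationError):
            build_body_mask(np.ones(myo.mask.shape), myo, outline, 1.5, 2.0)


class TestFitBiasSurface:
    def test_constant_reference_gives_unit_field(self):
        myo, outline = annulus_masks()
        ref = np.full(myo.mask.shape, 5.0)
        body = build_body_mask(ref, myo, outline)
        fit, bias = fit_bias_surface(ref, myo, body)
        np.testing.assert_allclose(bias.field, 1.0, atol=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_in_class_linear_gain_recovered_exactly(self):
        myo, outline = annulus_masks()
        ny, nx = myo.mask.shape
        x_norm = np.linspace(-1, 1, nx)[None, :] * np.ones((ny, 1))
        ref = 100.0 * (1.0 + 0.5 * x_norm)
        body = build_body_mask(ref, myo, outline)
        _, bias = fit_bias_surface(ref, myo, body)
        truth = BiasField.from_surface(1.0 + 0.5 * x_norm, myo)
        err = np.abs(bias.field / truth.field - 1.0)
        assert err.max() < 1e-6

    def test_ten_pixel_interpolation_case_has_zero_residual(self):
        ny = nx = 32
        rng = np.random.default_rng(5)
        y = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
        x = np.linspace(-1, 1, nx)[None, :] * np.ones((ny, 1))
        ref = 50.0 * (1.2 + 0.4 * x - 0.3 * y + 0.2 * x * y - 0.1 * y**3)
        assert ref.min() > 0
        # exactly 10 pixels in generic position, split across both masks
        pts = set()
        while len(pts) < 10:
            pts.add((int(rng.integers(ny)), int(rng.integers(nx))))
        pts = sorted(pts)
        myo_m = np.zeros((ny, nx), bool)
        body_m = np.zeros((ny, nx), bool)
        for i, (iy, ix) in enumerate(pts):
            (myo_m if i < 10 else body_m)[iy, ix] = True
        fit, _ = fit_bias_surface(
            ref, RoiMask(myo_m, "myocardium"), RoiMask(body_m, "body")
        )
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_geometry_rejected(self):
        # all pixels on one row: cubic design is rank deficient
        ny = nx = 32
        myo_m = np.zeros((ny, nx), bool)
        myo_m[5, 2:20] = True
        ref = np.ones((ny, nx))
        with pytest.raises(ValidationError, match="rank-deficient|degenerate"):
            fit_bias_surface(ref, RoiMask(myo_m, "myocardium"),
                             RoiMask(np.zeros((ny, nx), bool), "body"))

    def test_gain_recovery_under_rician_noise(self):
        """In-class cubic gain recovered within 2% relative RMS at SNR 20."""
        myo, outline = annulus_masks()
        ny, nx = myo.mask.shape
        y = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
        x = np.linspace(-1, 1, nx)[None, :] * np.ones((ny, 1))
        gain = 1.6 - 0.9 * y + 0.25 * x - 0.35 * x * y + 0.3 * y**2
        tissue = 0.5
        rng = np.random.default_rng(11)
        sigma = tissue * gain[myo.mask].mean() / 20.0
        errs = []
        for _ in range(25):
            ref = _rician(rng, tissue * gain, sigma)
            body = build_body_mask(ref, myo, outline)
            _, bias = fit_bias_surface(ref, myo, body)
            union = myo.mask | body.mask
            t = gain / gain[myo.mask].mean()
            errs.append(np.sqrt(np.mean(
                ((bias.field[union] - t[union]) / t[union]) ** 2)))
        assert np.mean(errs) < 0.02


class TestApplyAndNormalize:
    def test_unit_bias_is_identity(self, clean_study):
        bias = BiasField(np.ones(clean_study.perfusion.frame_shape))
        out = apply_scic(clean_study.perfusion, bias)
        np.testing.assert_array_equal(out.frames, clean_study.perfusion.frames)
        np.testing.assert_array_equal(out.times_s, clean_study.perfusion.times_s)

    def test_multiplicative_inverse_recovers_truth(self, rng):
        truth = rng.uniform(1.0, 2.0, (5, 8, 8))
        gain = rng.uniform(0.5, 3.0, (8, 8))
        series = DynamicSeries(frames=truth * gain[None],
                               times_s=np.arange(5.0))
        corrected = apply_scic(series, BiasField(gain))
        np.testing.assert_allclose(corrected.frames, truth, rtol=1e-12)

    def test_composition_equals_product(self, rng):
        series = DynamicSeries(frames=rng.uniform(1, 2, (3, 6, 6)),
                               times_s=np.arange(3.0))
        b1 = BiasField(rng.uniform(0.5, 2.0, (6, 6)))
        b2 = BiasField(rng.uniform(0.5, 2.0, (6, 6)))
        lhs = apply_scic(apply_scic(series, b1), b2)
        rhs = apply_scic(series, BiasField(b1.field * b2.field))
        np.testing.assert_allclose(lhs.frames, rhs.frames, rtol=1e-12)

    def test_baseline_normalization_sets_unit_baseline_and_is_idempotent(
        self, fast_study
    ):
        myo = fast_study.masks["myocardium"]
        normalized, scale = baseline_normalize(fast_study.perfusion, myo, 4)
        assert scale > 0
        assert normalized.frames[:4, myo.mask].mean() == pytest.approx(1.0)
        again, scale2 = baseline_normalize(normalized, myo, 4)
        assert scale2 == pytest.approx(1.0)
        np.testing.assert_allclose(again.frames, normalized.frames)

    def test_scalar_normalization_preserves_spatial_cov(self, fast_study):
        myo = fast_study.masks["myocardium"]
        frame = fast_study.perfusion.frames[0]
        before = cov_si(frame, myo)
        normalized, _ = baseline_normalize(fast_study.perfusion, myo, 4)
        after = cov_si(normalized.frames[0], myo)
        assert after == pytest.approx(before, rel=1e-12)


class TestRunScic:
    def test_pd_and_ssfp_fields_agree_for_uniform_tissue(self):
        spec = PhantomSpec.scaled_default(seed=2, grid=48, snr=None)
        perf, pd, aif, truth = generate_phantom(spec, uniform_signal())
        args = (perf, pd, truth.masks["myocardium"], truth.masks["body"])
        r_pd = run_scic("pd", *args)
        r_ss = run_scic("ssfp", *args)
        dev = np.abs(r_pd.bias.field / r_ss.bias.field - 1.0)
        assert dev.max() < 1e-3

    def test_no_scic_equals_pd_scic_downstream_for_uniform_gain(self):
        # uniform gain and uniform tissue: the fitted field is constant,
        # so after baseline normalization both arms coincide
        spec = PhantomSpec.scaled_default(
            seed=1, grid=48, snr=None, coil_gains=[((0.0, 24.0), 0.0, 24.0)]
        )
        perf, pd, aif, truth = generate_phantom(spec, uniform_signal())
        args = (perf, pd, truth.masks["myocardium"], truth.masks["body"])
        r_none = run_scic("none", *args)
        r_pd = run_scic("pd", *args)
        np.testing.assert_allclose(r_pd.series.frames, r_none.series.frames,
                                   rtol=1e-6, atol=1e-9)

    def test_pd_correction_reduces_reference_cov(self, fast_study):
        myo = fast_study.masks["myocardium"]
        result = run_scic("pd", fast_study.perfusion, fast_study.pd, myo,
                          fast_study.masks["body"])
        assert cov_si(result.reference_corrected, myo) < cov_si(
            result.reference, myo
        )

    def test_corrected_si_cov_ordering_across_replicates(self):
        """Corrected-PD <= corrected-SSFP <= uncorrected, nearly always."""
        wins = 0
        n = 20
        for seed in range(n):
            spec = PhantomSpec.scaled_default(seed=seed, grid=48, snr=20.0)
            perf, pd, aif, truth = generate_phantom(spec)
            myo = truth.masks["myocardium"]
            args = (perf, pd, myo, truth.masks["body"])
            cov_pd = cov_si(run_scic("pd", *args).reference_corrected, myo)
            r_ss = run_scic("ssfp", *args)
            cov_ss = cov_si(r_ss.reference_corrected, myo)
            cov_unc = cov_si(r_ss.reference, myo)
            wins += cov_pd <= cov_ss <= cov_unc
        assert wins >= 0.95 * n

    def test_mode_preconditions(self, fast_study):
        with pytest.raises(ValidationError, match="proton-density"):
            run_scic("pd", fast_study.perfusion, None,
                     fast_study.masks["myocardium"], fast_study.masks["body"])
        with pytest.raises(ValidationError, match="unknown SCIC mode"):
            ScicMode.parse("bogus")
        with pytest.raises(ValidationError, match="baseline frame"):
            run_scic("ssfp", fast_study.perfusion, fast_study.pd,
                     fast_study.masks["myocardium"], fast_study.masks["body"],
                     ssfp_frame_index=10)

    def test_preserves_times_masks_and_nonnegativity(self, fast_study):
        result = run_scic("pd", fast_study.perfusion, fast_study.pd,
                          fast_study.masks["myocardium"],
                          fast_study.masks["body"])
        np.testing.assert_array_equal(result.series.times_s,
                                      fast_study.perfusion.times_s)
        assert np.all(result.series.frames >= 0)
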