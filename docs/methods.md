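# Methods

This note documents the models, parameter choices and numerical
decisions behind `perfquant`, and what the phantom-based validation does
and does not establish.

## Pipeline overview

One mid-ventricular short-axis slice is processed per study:

1. **Surface-coil intensity correction (SCIC).**  The receive-coil gain
   is estimated from a reference image by ordinary least squares of a
   third-order 2D polynomial (10 coefficients) over the union of the
   myocardial ROI and a body ROI, on pixel coordinates affinely
   normalized to [-1, 1]^2 for conditioning.  The body ROI is the traced
   body outline restricted to pixels whose intensity lies within
   [0.5, 2.0] x the median myocardial intensity, which removes bright
   fat and dark lung that would otherwise be absorbed into the fitted
   surface.  The fitted surface is evaluated on the full grid, floored
   at 1e-3 x its mask-union mean so division cannot amplify noise where
   the extrapolated polynomial dips, and normalized to unit mean over
   the myocardium (so correction does not rescale mean myocardial
   signal; any consistent scalar would do because baseline
   normalization follows).  PD-SCIC uses the proton-density frame as
   reference; SSFP-SCIC uses the first pre-contrast saturation-prepared
   frame (frame 0 by default); No-SCIC skips the fit.  All three arms
   end with scalar baseline normalization: division by the mean
   myocardial signal of the first 4 (default) pre-contrast frames.
   Intensities are fitted on their raw scale (not log), and myocardial
   and body pixels are pooled unweighted.

2. **AIF extraction.**  The blood-pool mean curve of the low-resolution
   AIF series is converted to fractional enhancement
   (S - S_base)/S_base, which cancels the coil gain and equilibrium
   signal at the AIF location, then divided by the linearized
   enhancement-per-concentration slope of the AIF readout,
   beta = r1_relaxivity * TS * exp(-TS*R1_0) / (1 - exp(-TS*R1_0)),
   giving concentration in mmol/L in the linear regime.  The tissue
   side measures beta_tissue * C_t after baseline normalization, so the
   AIF is rescaled by beta_tissue before deconvolution; with both
   inputs on one scale the fitted response height is flow in physical
   units.  This mirrors dual-sequence practice, where known sequence
   parameters calibrate the two readouts to a common concentration
   scale.  Nonlinear saturation correction of the AIF is out of scope;
   the phantom's AIF readout is generated near-linear (see below).

3. **Contrast arrival.**  The foot of a curve is the first sample
   exceeding baseline_mean + max(3 x baseline_SD, 0.05 x rise), with
   baseline statistics from the first 4 frames.  The foot is detected
   once on the myocardial mean curve; each pixel is then
   baseline-subtracted against its own pre-foot mean and clipped at
   zero.

4. **Deconvolution.**  Tissue curves are fitted as the trapezoidal
   discrete convolution of the AIF with a Fermi retention response
   R(t) = amp / (1 + exp(k (t - delay - w))) for t >= delay (zero
   before).  MBF is read off as R(delay) = amp / (1 + exp(-k w)),
   multiplied by 60 / 1.05 to convert per-second, per-mL-tissue flow to
   mL/min/g (myocardial density 1.05 g/mL).  Fitting details:

   * **First-pass window.**  The Fermi model describes the first pass
     only, so the fit uses frames up to the point where the AIF falls
     below 30% of its peak (~19 of 60 frames with the default bolus).
     Fitting the full washout tail forces the sigmoid to track the
     tissue tail at the expense of its initial height and roughly
     doubles the cross-model flow bias (see validation below).
   * **Delay grid.**  On a uniform time grid, sub-sample delays are not
     identifiable — shifting delay and width together reproduces the
     sampled model exactly while changing the R(delay) read-out — so
     the delay is searched over integer multiples of the frame
     interval within [0, 10] s, with ties broken toward lower residual
     then lower delay.
   * **Optimization.**  A coarse candidate grid over (k, w, delay) with
     the amplitude profiled out linearly ranks starting points; the
     best `multistart` (default 3) candidates are refined by bounded
     trust-region least squares over (amp, k, w) at fixed delay.
     Bounds: amp in [0, 0.5] 1/s, k in [0.02, 5] 1/s, w in [0, 60] s.
     Pixel-wise maps use a vectorized variant: a dense (k, w, delay)
     grid (~5% resolution in k and w, amplitude profiled exactly per
     pixel) evaluated for all pixels at once; grid discretization
     contributes well under 1% to the MBF read-out, below the pixel
     noise level, and makes maps deterministic and fast.  Continuous
     refinement per pixel is available via `polish=True`.

5. **Regional statistics.**  Six 60-degree sectors anchored at the
   anterior RV insertion angle, clockwise anterior, anterolateral,
   inferolateral, inferior, inferoseptum, anteroseptum; territories
   LAD = {anterior, anteroseptum}, LCX = {anterolateral,
   inferolateral}, RCA = {inferior, inferoseptum}.  Myocardial signal
   CoV and MBF spatial heterogeneity are 100 x sample SD / mean (n-1
   denominator).  Septal-lateral difference is mean(anteroseptum,
   inferoseptum) - mean(anterolateral, inferolateral).  Territory means
   are unweighted means of sector means, so unequal sector areas do not
   bias them; remote and ischaemic means average the sectors of
   non-diseased and diseased territories.  Paired t-tests are the
   classical statistic with df = n - 1 and two-sided p; no
   multiple-testing correction is applied.  Whether remote/ischaemic
   means should be pixel-pooled rather than sector-averaged is not
   determinable from the comparison being emulated; sector averaging is
   the documented choice.

## The phantom

The generator emulates a dual-sequence stress perfusion acquisition on
a 128x128 grid (myocardial annulus radii 28/40 px, LV pool radius
20 px), 60 frames one R-R interval (1 s) apart, with a separate
low-resolution (2x block-averaged) AIF series acquired 60 ms before
each perfusion readout.  Scaled-down grids (48-64 px) keep replicate
experiments fast; all geometry scales proportionally.

* **Kinetics.**  The AIF is a gamma-variate bolus
  Ca(t) = K (t-t0)^a exp(-(t-t0)/b) with t0 = 8 s, a = 2.5, b = 1.8 s,
  peak 3.5 mmol/L (a compact low-dose bolus).  Tissue curves follow the
  one-compartment Kety model, impulse response f exp(-f t / vd) with
  vd = 0.15 mL/g and default stress flow 2.5 mL/min/g per territory.
  Generation uses Kety while quantification fits Fermi *by design*: a
  Fermi-generated phantom would make parameter-recovery tests circular.
* **Signal model.**  A generic saturation-recovery stand-in
  S = s0 (1 - exp(-TS (R1_0 + r C))) per tissue class with r =
  4.5 /mmol/s, TS = 30 ms for the perfusion readout and an effectively
  linear TS = 2 ms for the AIF readout; the PD frame is 0.5 x s0 with
  no saturation weighting.  TS = 30 ms keeps peak-enhancement
  saturation of tissue curves to a few percent, consistent with the
  pipeline's linear concentration conversion; users emulating stronger
  saturation should substitute their own parameters and a nonlinear
  conversion.
* **Chest structure.**  The body ellipse contains a bright short-T1
  subcutaneous fat rim (excluded by the body-ROI band in both reference
  images), dark lateral lungs (likewise excluded), and a liver region
  inferior to the heart whose R1 contrast is mild in the PD frame but
  ~1.8x in the saturation-prepared frame.  This reproduces the
  mechanism that makes the SSFP reference the harder fitting target:
  saturation weighting turns tissue T1 differences into intensity
  structure that a smooth surface fit partially absorbs into the gain
  estimate, while the PD reference carries mostly proton-density
  contrast (and ~5-15x higher effective SNR).
* **Coil gain.**  One exponential lobe 1 + A exp(-d/decay) anchored
  just above the anterior chest wall, offset toward the septal side
  (A = 7, decay = 0.30 x grid); over the myocardium the anterior:inferior
  sextant gain ratio is ~2.2, matching the reported anterior/ventral
  signal weighting of phased-array coils.
* **Noise.**  Rician (magnitude-image) noise with sigma defined as
  baseline myocardial signal / SNR, default SNR 20; the AIF series gets
  its own sigma relative to its baseline blood signal.  A given seed
  yields bit-identical studies.

## Validation results the tests establish

* The surface fit recovers an in-class cubic gain exactly (relative RMS
  ~1e-16) and to ~0.3% mean relative RMS at SNR 20 — thousands of
  fitted pixels anchor ten coefficients, so reference noise propagates
  weakly.
* Fermi-generated curves are recovered to ~1e-12 relative (the fit is
  in-class).  Kety-generated flows of 0.5-3 mL/min/g are recovered with
  a flow-dependent bias of -1% to -8% noise-free — the honest cost of
  the model mismatch plus the initial-height read-out — and pixel-level
  MAE of 6-9% at SNR 20.
* On uniform-flow phantoms at SNR 20, MBF heterogeneity orders
  No-SCIC (~34%) > SSFP-SCIC (~10%) > PD-SCIC (~7%) in every seeded
  replicate, and the corrected-PD reference CoV always beats the
  uncorrected one.
* With a 30% LAD flow deficit, both corrections recover a positive
  remote-ischaemic difference within ~20% of truth, while No-SCIC
  yields a *negative* difference in every replicate — the sign
  reversal that makes uncorrected pixel-wise quantification clinically
  misleading.

## What the phantom does not show

The phantom is motion-free (registration is out of scope), single
slice, free of dark-rim and parallel-imaging artifacts, has piecewise
constant tissue classes, no physiologic flow heterogeneity, no
recirculation, and its gain field is a smooth single-lobe model.
Passing these tests demonstrates the pipeline's internal consistency
and the directional effects of coil gain on quantification; it does not
calibrate absolute accuracy on patient data, where motion, AIF
saturation, and real coil geometry add errors the phantom does not
model.  Healthy human myocardium also has intrinsic MBF heterogeneity
(~16% by animal data), so in-vivo heterogeneity values sit well above
the phantom's noise-driven floor.

## Problem sizes

Replicate experiments use scaled-down grids chosen once: bias-field
recovery on 64x64 (100 replicates), the heterogeneity ordering on
48x48 (100 replicates, all three arms quantified per replicate), the
disease-cohort reproduction on 64x64 (8 healthy + 12 disease
phantoms), all at 60 frames and SNR 20.  The acceptance script and the
test suite both run these sizes end to end on one CPU in a few
minutes.
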