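# perfquant

Pixel-wise myocardial blood flow (MBF) quantification for first-pass
contrast-enhanced cardiac MR, with surface-coil intensity correction
(SCIC) and a digital perfusion phantom.

## The problem

Quantitative perfusion CMR estimates MBF (mL/min/g) per myocardial pixel
by deconvolving the arterial input function (AIF) from tissue
enhancement curves.  Phased-array receive coils impose a smooth
multiplicative gain g(x, y) on every image — anterior (chest-wall-near)
myocardium can appear 2-3x brighter than inferior myocardium.  Because a
single AIF serves the whole slice, that gain multiplies straight into
the per-pixel flow estimate: uncorrected maps show spurious spatial
heterogeneity and can even *invert* the contrast between tissue supplied
by a stenosed coronary artery and remote tissue, so that the diseased
territory appears the best perfused.  This package implements the
quantification pipeline with three correction arms and the statistics to
compare them:

* **PD-SCIC** — estimate g from a proton-density-weighted reference
  frame by a third-order 2D polynomial surface fit over myocardial and
  body ROIs, divide the series by it;
* **SSFP-SCIC** — same fit on the first pre-contrast saturation-prepared
  SSFP frame;
* **No-SCIC** — scalar baseline normalization only.

## The model

Tissue contrast is modelled as `C_t(t) = (C_a * h)(t)` with a Fermi
impulse retention response

    h(t) = A / (1 + exp(k (t - t0 - w)))   for t >= t0,  0 before,

fitted per pixel by bounded least squares over the first pass (frames
where the AIF exceeds 30% of its peak), with the arrival delay t0
searched over integer multiples of the frame interval.  MBF is the
response's initial height `h(t0) = A / (1 + exp(-k w))`, converted to
mL/min/g with a myocardial density of 1.05 g/mL.  Contrast concentration
comes from baseline-subtracted signal (linear conversion), with AIF and
tissue placed on one scale via the linearized saturation-recovery
enhancement slope.

The bundled phantom generates the full dual-sequence acquisition —
60-frame saturation-recovery SSFP series, PD reference frame,
low-resolution AIF series — over a short-axis geometry with a structured
chest (fat rim, lungs, liver), a known anterior-weighted coil gain,
per-territory flows from one-compartment Kety kinetics (deliberately a
*different* kinetic model than the quantifier fits), and Rician noise.
Ground truth (flow map, gain field, AIF, segment labels) is emitted
alongside, so every stage is testable without patient data.

## Worked example

Reproduce the core comparison — 8 healthy phantoms plus 12 phantoms with
a 30% LAD-territory flow deficit, quantified with all three arms:

```bash
python analysis/05_ischaemia_detection.py --seed 1
```

prints

```
ground-truth remote-ischaemic difference: 0.75 mL/min/g
     mode  remote_mbf_ml_min_g  ischaemic_mbf_ml_min_g  difference_ml_min_g  difference_sd
  PD-SCIC                2.246                   1.626                0.620          0.008
SSFP-SCIC                2.242                   1.630                0.612          0.011
  No-SCIC                1.798                   2.273               -0.476          0.010
12/12 disease phantoms show a reversed (negative) difference without correction
```

With either correction the remote-minus-ischaemic difference is positive
and close to the simulated truth; without correction the anterior coil
gain inflates apparent LAD-territory flow so strongly that the
difference *changes sign* — the diseased territory looks the best
perfused.  The healthy cohort shows the same story in heterogeneity
terms (`analysis/04_scic_comparison.py`): MBF spatial heterogeneity is
~34% without correction versus ~7% (PD) and ~10% (SSFP).

Other drivers: `01_simulate_phantom.py` writes a reference phantom with
ground truth, `02_bias_field_recovery.py` and `03_mbf_recovery.py`
quantify bias-field and flow recovery accuracy.  The same pipeline is
scriptable as a CLI: `perfquant simulate|correct|quantify|report|run-all`
(see `perfquant --help`); `run-all` produces a fully reproducible output
tree (corrected series, bias fields, MBF maps, report.json, manifest)
from one seeded config.

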