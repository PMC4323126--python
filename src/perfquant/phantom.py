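"""Digital dual-sequence perfusion phantom with known ground truth.

Generates a synthetic first-pass perfusion study — a saturation-recovery
SSFP dynamic series, a proton-density reference frame, and a separate
low-resolution AIF series — over a simple short-axis geometry (body
ellipse, LV blood pool, myocardial annulus), with a known multiplicative
coil-gain field, per-territory myocardial blood flow, and Rician noise.

Generator-side tissue kinetics use the one-compartment Kety model
(mono-exponential impulse response) while the quantifier fits a Fermi
model; the deliberate mismatch keeps parameter-recovery tests honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConcentrationCurve, DynamicSeries, RoiMask, SegmentLabels, ValidationError
from .kinetics import TISSUE_DENSITY_G_PER_ML, trapz_convolve
from .regional_stats import SEGMENT_TERRITORY, sectorize

#: acquisition offset of the perfusion readout after the AIF readout, s
PERFUSION_READOUT_OFFSET_S = 0.06


def anterior_coil_preset(grid_shape: tuple[int, int], amplitude: float = 7.0) -> list:
    """Anterior-weighted gain lobes for a given grid.

    One exponential lobe just above the chest wall, offset toward the
    septal side, emulating the higher anterior/ventral signal of a
    phased-array receive coil.  With the default amplitude the mean gain
    over the anterior myocardial sextant exceeds twice the mean over the
    inferior sextant on the default geometry.
    """
    ny, nx = grid_shape
    return [((-0.05 * ny, 0.30 * nx), amplitude, 0.30 * ny)]


def uniform_coil_preset(grid_shape: tuple[int, int]) -> list:
    """A single zero-amplitude lobe: gain identically 1."""
    ny, nx = grid_shape
    return [((0.0, 0.5 * nx), 0.0, 0.5 * ny)]


@dataclass
class PhantomSpec:
    """Geometry, kinetics, coil and noise settings of a synthetic study.

    Distances are in pixels; the default geometry is a 128x128 grid with a
    myocardial annulus of radii 28/40 px, 60 frames one R-R interval
    (1 s) apart, a 0.05 mmol/kg-like compact bolus, and uniform stress-level
    flow of 2.5 mL/min/g in all three coronary territories.
    """

    seed: int
    grid_shape: tuple[int, int] = (128, 128)
    myo_center_px: tuple[float, float] | None = None
    myo_radii_px: tuple[float, float] = (28.0, 40.0)
    lv_radius_px: float = 20.0
    body_ellipse_px: tuple[float, float] = (52.0, 60.0)
    rv_insertion_angle_deg: float = 330.0
    n_frames: int = 60
    rr_interval_s: float = 1.0
    aif_params: tuple[float, float, float, float] = (8.0, 2.5, 1.8, 3.5)
    territory_mbf: dict = field(
        default_factory=lambda: {"LAD": 2.5, "LCX": 2.5, "RCA": 2.5}
    )
    vd_ml_per_g: float = 0.15
    coil_gains: list | None = None
    snr: float | None = 20.0
    aif_downsample: int = 2

    def __post_init__(self) -> None:
        ny, nx = self.grid_shape
        if self.myo_center_px is None:
            self.myo_center_px = (ny / 2.0, nx / 2.0)
        r_in, r_out = self.myo_radii_px
        if not (0 < self.lv_radius_px < r_in < r_out):
            raise ValidationError(
                "radii must be positive and nested: lv < inner < outer"
            )
        if any(f < 0 for f in self.territory_mbf.values()):
            raise ValidationError("territory flows must be >= 0")
        if set(self.territory_mbf) != {"LAD", "LCX", "RCA"}:
            raise ValidationError("territory_mbf must map exactly LAD, LCX, RCA")
        if self.vd_ml_per_g <= 0:
            raise ValidationError("vd must be > 0")
        if self.n_frames < 10:
            raise ValidationError("n_frames must be >= 10")
        t0, alpha, beta, peak = self.aif_params
        if alpha <= 0 or beta <= 0:
            raise ValidationError("AIF shape parameters must be positive")
        if peak <= 0:
            raise ValidationError("AIF peak concentration must be positive")
        if self.coil_gains is None:
            self.coil_gains = anterior_coil_preset(self.grid_shape)

    @classmethod
    def scaled_default(cls, seed: int, grid: int = 128, **overrides) -> "PhantomSpec":
        """Default spec with all geometry scaled to an NxN grid."""
        s = grid / 128.0
        params = dict(
            seed=seed,
            grid_shape=(grid, grid),
            myo_radii_px=(28.0 * s, 40.0 * s),
            lv_radius_px=20.0 * s,
            body_ellipse_px=(52.0 * s, 60.0 * s),
        )
        if "coil_gains" not in overrides:
            params["coil_gains"] = anterior_coil_preset((grid, grid))
        params.update(overrides)
        return cls(**params)


@dataclass
class SignalModelParams:
    """Stand-in saturation-recovery signal model for the synthetic readout.

    ``S = s0 * (1 - exp(-ts * (r1_0 + r * C)))`` per tissue class; the PD
    frame is ``pd_scale * s0`` (no saturation weighting); the AIF series
    uses a much shorter effective saturation delay ``aif_ts_s`` so its
    signal is near-linear in concentration.  Values are generic
    literature-scale stand-ins, not a fit to any particular scanner;
    substitute your own to emulate a different acquisition.
    """

    ts_s: float = 0.03
    aif_ts_s: float = 0.002
    r1_0_per_s: dict = field(
        default_factory=lambda: {
            "myocardium": 1.0,
            "blood": 0.66,
            "body": 1.0,     # chest-wall / skeletal muscle
            "fat": 3.3,      # short-T1 subcutaneous fat
            "liver": 1.7,
            "lung": 1.0,
        }
    )
    r1_relaxivity_per_mmol_s: float = 4.5
    s0: dict = field(
        default_factory=lambda: {
            "myocardium": 1.0,
            "blood": 1.05,
            "body": 0.85,
            "fat": 3.2,      # markedly brighter than myocardium
            "liver": 0.9,
            "lung": 0.08,    # air-dominated, markedly darker
        }
    )
    pd_scale: float = 0.5

    def __post_init__(self) -> None:
        scalars = [self.ts_s, self.aif_ts_s, self.r1_relaxivity_per_mmol_s,
                   self.pd_scale]
        if any(v <= 0 for v in scalars):
            raise ValidationError("signal model scalars must be positive")
        for d in (self.r1_0_per_s, self.s0):
            if any(v <= 0 for v in d.values()):
                raise ValidationError("per-class signal parameters must be positive")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a generated study."""

    mbf_true: np.ndarray
    gain_true: np.ndarray
    masks: dict
    aif_true: ConcentrationCurve
    segment_labels: SegmentLabels
    spec: PhantomSpec
    signal: SignalModelParams

    def __post_init__(self) -> None:
        if np.any(self.gain_true <= 0):
            raise ValidationError("gain_true must be strictly positive")


# ---------------------------------------------------------------------------
# Component models
# ---------------------------------------------------------------------------


def gamma_variate_aif(
    aif_params: tuple[float, float, float, float],
    times_s: np.ndarray,
) -> ConcentrationCurve:
    """Gamma-variate bolus model for the arterial input function.

    ``Ca(t) = K * (t - t0)^alpha * exp(-(t - t0)/beta)`` for t > t0, else
    0, with K chosen so the maximum equals ``peak_mmol_per_L`` (attained
    at ``t0 + alpha*beta``).
    """
    t0, alpha, beta, peak = aif_params
    if alpha <= 0 or beta <= 0:
        raise ValidationError("gamma-variate shape parameters must be positive")
    t = np.asarray(times_s, dtype=np.float64)
    tau = np.clip(t - t0, 0.0, None)
    # normalized form: (tau/(alpha*beta))^alpha * exp(alpha - tau/beta) peaks at 1
    with np.errstate(divide="ignore", invalid="ignore"):
        values = peak * (tau / (alpha * beta)) ** alpha * np.exp(alpha - tau / beta)
    values = np.where(tau > 0, values, 0.0)
    above = np.nonzero(t > t0)[0]
    foot = int(above[0]) if above.size else None
    return ConcentrationCurve(values=values, times_s=t, foot_index=foot)


def kety_flow_rates(f_ml_min_g: float, vd_ml_per_g: float) -> tuple[float, float]:
    """(impulse amplitude 1/s, washout rate 1/s) of the Kety response.

    The amplitude converts flow per gram to flow per mL of tissue
    (density 1.05 g/mL) and per second; the washout rate is f/vd per
    minute.
    """
    amp = f_ml_min_g * TISSUE_DENSITY_G_PER_ML / 60.0
    rate = f_ml_min_g / (vd_ml_per_g * 60.0)
    return amp, rate


def kety_tissue_curve(
    aif: ConcentrationCurve,
    f_ml_min_g: float,
    vd_ml_per_g: float,
) -> ConcentrationCurve:
    """One-compartment Kety tissue curve by discrete convolution.

    ``Ct = Ca (*) R`` with ``R(t) = f * exp(-f t / vd)`` (f converted to
    per-second, per-mL-tissue units), trapezoidal quadrature on the AIF's
    uniform time grid.
    """
    if f_ml_min_g < 0:
        raise ValidationError("flow must be >= 0")
    if vd_ml_per_g <= 0:
        raise ValidationError("vd must be > 0")
    t = aif.times_s - aif.times_s[0]
    dts = np.diff(t)
    if dts.size == 0:
        raise ValidationError("need at least 2 samples")
    if (dts.max() - dts.min()) > 1e-6 * dts.mean():
        raise ValidationError("kety_tissue_curve requires a uniform time grid")
    dt = float(dts.mean())
    amp, rate = kety_flow_rates(f_ml_min_g, vd_ml_per_g)
    response = amp * np.exp(-rate * t)
    values = trapz_convolve(aif.values, response, dt)
    return ConcentrationCurve(values=values, times_s=aif.times_s,
                              foot_index=aif.foot_index)


def sr_signal(conc, params: SignalModelParams, tissue_class: str, ts_s: float | None = None):
    """Saturation-recovery signal for a concentration (scalar or array).

    ``S = s0 * (1 - exp(-ts * (r1_0 + r * C)))``: monotone increasing and
    saturating toward s0 as C grows.
    """
    conc = np.asarray(conc, dtype=np.float64)
    if np.any(conc < 0):
        raise ValidationError("concentration must be >= 0")
    ts = params.ts_s if ts_s is None else ts_s
    r1 = params.r1_0_per_s[tissue_class] + params.r1_relaxivity_per_mmol_s * conc
    out = params.s0[tissue_class] * -np.expm1(-ts * r1)
    return float(out) if out.ndim == 0 else out


def coil_gain_field(coil_gains: list, grid_shape: tuple[int, int]) -> np.ndarray:
    """Multiplicative gain field from exponential lobes.

    ``g(y, x) = 1 + sum_i amplitude_i * exp(-dist((y,x), pos_i)/decay_i)``;
    strictly positive by construction.
    """
    if not coil_gains:
        raise ValidationError("need at least one gain lobe")
    ny, nx = grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    g = np.ones((ny, nx))
    for (py, px), amplitude, decay in coil_gains:
        if decay <= 0:
            raise ValidationError("lobe decay must be positive")
        dist = np.hypot(yy - py, xx - px)
        g += amplitude * np.exp(-dist / decay)
    return g


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


#: tissue classes rendered with a constant (zero-contrast) signal
_STATIC_CLASSES = ("body", "fat", "liver", "lung")


def _geometry(spec: PhantomSpec):
    """Class masks: heart annulus/pool plus a structured chest.

    Beyond the heart, the body carries realistic substructure — a bright
    short-T1 subcutaneous fat rim, dark lateral lungs and a liver region
    inferior to the heart — so the reference images used for bias-field
    fitting contain the abrupt intensity transitions that make surface
    coil correction hard in vivo (and that the body-ROI intensity band is
    designed to exclude).
    """
    ny, nx = spec.grid_shape
    cy, cx = spec.myo_center_px
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    r = np.hypot(yy - cy, xx - cx)
    r_in, r_out = spec.myo_radii_px
    myo = (r >= r_in) & (r < r_out)
    blood = r <= spec.lv_radius_px
    by, bx = spec.body_ellipse_px
    ellipse = ((yy - cy) / by) ** 2 + ((xx - cx) / bx) ** 2
    body_outline = ellipse <= 1.0
    if int(myo.sum()) < 10:
        raise ValidationError("geometry leaves < 10 myocardial pixels")

    heart = r < r_out
    fat = body_outline & (ellipse > 0.88) & ~heart

    def sub_ellipse(cy0, cx0, ay, ax):
        return ((yy - cy0) / ay) ** 2 + ((xx - cx0) / ax) ** 2 <= 1.0

    lung = np.zeros_like(myo)
    for side in (-1.0, 1.0):
        lung |= sub_ellipse(cy - 0.05 * by, cx + side * 0.72 * bx,
                            0.45 * by, 0.16 * bx)
    liver = sub_ellipse(cy + 0.80 * by, cx - 0.25 * bx, 0.30 * by, 0.50 * bx)

    inside = body_outline & ~heart & ~blood
    masks = {
        "myocardium": myo,
        "blood": blood,
        "lung": inside & lung & ~fat,
        "liver": inside & liver & ~lung & ~fat,
        "fat": inside & fat,
    }
    assigned = np.zeros_like(myo)
    for m in masks.values():
        assigned |= m
    masks["body"] = inside & ~assigned
    masks["body_outline"] = body_outline
    return masks


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def _block_mean(img: np.ndarray, ds: int) -> np.ndarray:
    ny, nx = img.shape[-2:]
    ny2, nx2 = (ny // ds) * ds, (nx // ds) * ds
    img = img[..., :ny2, :nx2]
    shape = img.shape[:-2] + (ny2 // ds, ds, nx2 // ds, ds)
    return img.reshape(shape).mean(axis=(-3, -1))


def generate_phantom(
    spec: PhantomSpec,
    signal: SignalModelParams | None = None,
):
    """Generate a synthetic dual-sequence study with ground truth.

    Returns ``(perfusion, pd, aif, truth)``: the perfusion
    :class:`DynamicSeries`, the single-frame PD series, the
    low-resolution AIF series, and a :class:`PhantomTruth`.

    Every pixel's tissue class follows from the geometry; myocardial
    pixels carry Kety tissue curves with their territory's flow, blood
    pixels carry the gamma-variate AIF, all signals pass through the
    saturation-recovery readout and are multiplied by the coil gain, and
    Rician noise is added at the requested baseline-myocardium SNR.  The
    same seed yields bit-identical outputs.
    """
    signal = signal or SignalModelParams()
    geo = _geometry(spec)
    myo, blood, body_outline = geo["myocardium"], geo["blood"], geo["body_outline"]
    gain = coil_gain_field(spec.coil_gains, spec.grid_shape)

    n = spec.n_frames
    aif_times = np.arange(n) * spec.rr_interval_s
    perf_times = aif_times + PERFUSION_READOUT_OFFSET_S

    aif_true = gamma_variate_aif(spec.aif_params, aif_times)
    ca_perf = gamma_variate_aif(spec.aif_params, perf_times)

    labels = sectorize(
        RoiMask(mask=myo, label="myocardium"),
        spec.myo_center_px,
        spec.rv_insertion_angle_deg,
    )
    flow_of_segment = {
        seg: spec.territory_mbf[terr] for seg, terr in SEGMENT_TERRITORY.items()
    }

    ny, nx = spec.grid_shape
    frames = np.zeros((n, ny, nx))
    for cls in _STATIC_CLASSES:
        frames[:, geo[cls]] = sr_signal(0.0, signal, cls)
    frames[:, blood] = sr_signal(ca_perf.values, signal, "blood")[:, None]

    mbf_true = np.full((ny, nx), np.nan)
    tissue_curves: dict[float, np.ndarray] = {}
    aif_grid_tissue: dict[float, np.ndarray] = {}
    for seg in range(1, 7):
        f = flow_of_segment[seg]
        if f not in tissue_curves:
            ct = kety_tissue_curve(ca_perf, f, spec.vd_ml_per_g)
            tissue_curves[f] = sr_signal(ct.values, signal, "myocardium")
            # AIF-series rendering of the myocardium, on the AIF time grid
            ct_aif = np.interp(aif_times, perf_times, ct.values)
            ct_aif = np.clip(ct_aif, 0.0, None)
            aif_grid_tissue[f] = sr_signal(ct_aif, signal, "myocardium",
                                           ts_s=signal.aif_ts_s)
        sel = labels.labels == seg
        frames[:, sel] = tissue_curves[f][:, None]
        mbf_true[sel] = f

    frames *= gain[None]

    pd_frame = np.zeros((ny, nx))
    for cls in _STATIC_CLASSES:
        pd_frame[geo[cls]] = signal.pd_scale * signal.s0[cls]
    pd_frame[blood] = signal.pd_scale * signal.s0["blood"]
    pd_frame[myo] = signal.pd_scale * signal.s0["myocardium"]
    pd_frame *= gain

    # low-resolution AIF series: near-linear readout, then block-downsampling
    aif_frames = np.zeros((n, ny, nx))
    for cls in _STATIC_CLASSES:
        aif_frames[:, geo[cls]] = sr_signal(0.0, signal, cls, ts_s=signal.aif_ts_s)
    aif_frames[:, blood] = sr_signal(aif_true.values, signal, "blood",
                                     ts_s=signal.aif_ts_s)[:, None]
    for seg in range(1, 7):
        sel = labels.labels == seg
        aif_frames[:, sel] = aif_grid_tissue[flow_of_segment[seg]][:, None]
    aif_frames *= gain[None]
    aif_frames = _block_mean(aif_frames, spec.aif_downsample)

    if spec.snr is not None:
        rng = np.random.default_rng(spec.seed)
        base_myo = sr_signal(0.0, signal, "myocardium") * gain[myo]
        sigma = float(base_myo.mean()) / spec.snr
        frames = _rician(rng, frames, sigma)
        pd_frame = _rician(rng, pd_frame, sigma)
        base_blood_aif = sr_signal(0.0, signal, "blood", ts_s=signal.aif_ts_s)
        sigma_aif = float(base_blood_aif * _block_mean(gain, spec.aif_downsample).mean()) / spec.snr
        aif_frames = _rician(rng, aif_frames, sigma_aif)

    spacing = (360.0 / ny, 360.0 / nx)
    perfusion = DynamicSeries(frames=frames, times_s=perf_times,
                              pixel_spacing_mm=spacing, series_role="perfusion")
    pd_series = DynamicSeries(frames=pd_frame[None], times_s=np.array([0.0]),
                              pixel_spacing_mm=spacing, series_role="pd")
    ds = spec.aif_downsample
    aif_series = DynamicSeries(frames=aif_frames, times_s=aif_times,
                               pixel_spacing_mm=(spacing[0] * ds, spacing[1] * ds),
                               series_role="aif")
    truth = PhantomTruth(
        mbf_true=mbf_true,
        gain_true=gain,
        masks={
            "myocardium": RoiMask(mask=myo, label="myocardium"),
            "body": RoiMask(mask=body_outline, label="body"),
            "blood_pool": RoiMask(mask=blood, label="blood_pool"),
        },
        aif_true=aif_true,
        segment_labels=labels,
        spec=spec,
        signal=signal,
    )
    return perfusion, pd_series, aif_series, truth
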