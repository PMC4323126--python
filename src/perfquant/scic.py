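"""Surface-coil intensity correction (SCIC) by polynomial surface fitting.

The receive-coil sensitivity of a phased array imposes a smooth
multiplicative gain on every frame.  Over tissue of similar intrinsic
signal (myocardium plus a band-limited body region), the reference image
is approximately proportional to that gain, so an ordinary least-squares
third-order 2D polynomial fit to reference intensities estimates the bias
field.  The reference is either the proton-density frame (PD-SCIC) or the
first pre-contrast saturation-prepared SSFP frame (SSFP-SCIC); without
correction (No-SCIC) only scalar baseline normalization is applied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import BiasField, DynamicSeries, RoiMask, ValidationError


class ScicMode(enum.Enum):
    """The three correction arms compared by the analysis."""

    PD_SCIC = "pd"
    SSFP_SCIC = "ssfp"
    NO_SCIC = "none"

    @classmethod
    def parse(cls, value) -> "ScicMode":
        if isinstance(value, cls):
            return value
        for mode in cls:
            if value in (mode.value, mode.name, mode.name.lower()):
                return mode
        raise ValidationError(f"unknown SCIC mode {value!r}")


@dataclass
class SurfaceFit:
    """A fitted 2D polynomial surface on normalized coordinates.

    ``coefficients[m]`` multiplies ``x_norm^i * y_norm^j`` for the m-th
    term of the degree-``order`` basis (i + j <= order, 10 terms for a
    cubic); ``coord_transform`` holds the affine pixel-to-[-1,1] maps
    ``(y_offset, y_scale, x_offset, x_scale)``.
    """

    coefficients: np.ndarray
    coord_transform: tuple[float, float, float, float]
    rms_residual: float
    order: int = 3

    def __post_init__(self) -> None:
        n_terms = (self.order + 1) * (self.order + 2) // 2
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).ravel()
        if self.coefficients.size != n_terms:
            raise ValidationError(
                f"expected {n_terms} coefficients for order {self.order}, "
                f"got {self.coefficients.size}"
            )
        oy, sy, ox, sx = self.coord_transform
        if sy == 0 or sx == 0:
            raise ValidationError("coord_transform must be invertible")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the surface on a full pixel grid of the given shape."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        oy, sy, ox, sx = self.coord_transform
        values = _design_matrix(
            (yy.ravel() - oy) * sy, (xx.ravel() - ox) * sx, self.order
        ) @ self.coefficients
        return values.reshape(shape)


def _poly_exponents(order: int) -> list[tuple[int, int]]:
    return [(i, j) for total in range(order + 1)
            for i in range(total + 1) for j in [total - i]]


def _design_matrix(y_norm: np.ndarray, x_norm: np.ndarray, order: int) -> np.ndarray:
    cols = [x_norm**i * y_norm**j for i, j in _poly_exponents(order)]
    return np.stack(cols, axis=1)


def _normalizers(shape: tuple[int, int]):
    ny, nx = shape
    oy, sy = (ny - 1) / 2.0, 2.0 / max(ny - 1, 1)
    ox, sx = (nx - 1) / 2.0, 2.0 / max(nx - 1, 1)
    return oy, sy, ox, sx


def build_body_mask(
    reference: np.ndarray,
    myo_mask: RoiMask,
    body_outline: RoiMask,
    lo_frac: float = 0.5,
    hi_frac: float = 2.0,
) -> RoiMask:
    """Band-limit the body outline to myocardium-like signal intensities.

    Keeps pixels inside the body outline, outside the myocardium, whose
    intensity lies in ``[lo_frac*m, hi_frac*m]`` where ``m`` is the median
    myocardial intensity — excluding regions markedly brighter (fat) or
    darker (lungs) than myocardium.
    """
    if not (0 < lo_frac < 1 < hi_frac):
        raise ValidationError("need 0 < lo_frac < 1 < hi_frac")
    reference = np.asarray(reference, dtype=np.float64)
    m = float(np.median(reference[myo_mask.mask]))
    band = (reference >= lo_frac * m) & (reference <= hi_frac * m)
    mask = body_outline.mask & ~myo_mask.mask & band
    if not mask.any():
        raise ValidationError("body mask empty after intensity banding")
    return RoiMask(mask=mask, label="body")


def fit_bias_surface(
    reference: np.ndarray,
    myo_mask: RoiMask,
    body_mask: RoiMask,
    order: int = 3,
    floor_frac: float = 1e-3,
) -> tuple[SurfaceFit, BiasField]:
    """Estimate the coil bias field from a reference frame.

    Ordinary least squares of a degree-``order`` polynomial (on
    coordinates affinely normalized to [-1, 1] squared) to reference
    intensities over the union of the myocardial and body masks.  The
    fitted surface is evaluated on the full grid, floored at
    ``floor_frac`` times its mask-union mean (so division cannot blow up
    where the extrapolated surface dips), and normalized to unit mean
    over the myocardium.
    """
    reference = np.asarray(reference, dtype=np.float64)
    if np.any(reference[myo_mask.mask | body_mask.mask] < 0):
        raise ValidationError("reference intensities must be >= 0")
    myo_mask.require_fit_pixels()
    union = myo_mask.mask | body_mask.mask
    n_terms = (order + 1) * (order + 2) // 2
    n_px = int(union.sum())
    if n_px < max(n_terms, 10):
        raise ValidationError(
            f"only {n_px} usable pixels; need >= {max(n_terms, 10)}"
        )
    yy, xx = np.nonzero(union)
    oy, sy, ox, sx = _normalizers(reference.shape)
    design = _design_matrix((yy - oy) * sy, (xx - ox) * sx, order)
    target = reference[union]
    coeffs, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < n_terms:
        raise ValidationError(
            "rank-deficient surface fit: degenerate mask geometry"
        )
    residual = design @ coeffs - target
    fit = SurfaceFit(
        coefficients=coeffs,
        coord_transform=(oy, sy, ox, sx),
        rms_residual=float(np.sqrt(np.mean(residual**2))),
        order=order,
    )
    surface = fit.evaluate(reference.shape)
    floor = floor_frac * float(surface[union].mean())
    if floor <= 0:
        raise ValidationError("fitted surface has non-positive mean over masks")
    surface = np.maximum(surface, floor)
    bias = BiasField.from_surface(surface, myo_mask)
    return fit, bias


def apply_scic(series: DynamicSeries, bias: BiasField) -> DynamicSeries:
    """Divide every frame by the bias field; timing/metadata unchanged."""
    if bias.field.shape != series.frame_shape:
        raise ValidationError(
            f"bias shape {bias.field.shape} != frame shape {series.frame_shape}"
        )
    return series.with_frames(series.frames / bias.field[None])


def baseline_normalize(
    series: DynamicSeries,
    myo_mask: RoiMask,
    n_baseline: int = 4,
) -> tuple[DynamicSeries, float]:
    """Divide the series by its mean myocardial baseline signal.

    The scalar is the mean intensity over the myocardial mask across the
    first ``n_baseline`` frames (which must precede contrast arrival).
    Returns the normalized series and the scalar.
    """
    if not 1 <= n_baseline < series.n_frames:
        raise ValidationError(
            f"n_baseline must be in [1, {series.n_frames - 1}], got {n_baseline}"
        )
    scale = float(series.frames[:n_baseline, myo_mask.mask].mean())
    if scale <= 0:
        raise ValidationError("non-positive baseline scale")
    return series.with_frames(series.frames / scale), scale


@dataclass
class ScicResult:
    """Output of one correction arm applied to a perfusion study."""

    mode: ScicMode
    series: DynamicSeries
    baseline_scale: float
    bias: BiasField | None = None
    surface_fit: SurfaceFit | None = None
    body_mask: RoiMask | None = None
    reference: np.ndarray | None = None
    reference_corrected: np.ndarray | None = None


def run_scic(
    mode: ScicMode | str,
    perfusion: DynamicSeries,
    pd: DynamicSeries | None,
    myo_mask: RoiMask,
    body_outline: RoiMask,
    n_baseline: int = 4,
    order: int = 3,
    lo_frac: float = 0.5,
    hi_frac: float = 2.0,
    ssfp_frame_index: int = 0,
) -> ScicResult:
    """Dispatch one of the three correction arms.

    PD_SCIC fits the bias surface on the proton-density frame; SSFP_SCIC
    fits it on the first pre-contrast saturation-prepared frame
    (``ssfp_frame_index``); both then divide the perfusion series by the
    field and apply baseline normalization.  NO_SCIC applies baseline
    normalization only.
    """
    mode = ScicMode.parse(mode)
    if mode is ScicMode.NO_SCIC:
        series, scale = baseline_normalize(perfusion, myo_mask, n_baseline)
        return ScicResult(mode=mode, series=series, baseline_scale=scale)

    if mode is ScicMode.PD_SCIC:
        if pd is None:
            raise ValidationError("PD_SCIC requires a proton-density frame")
        reference = pd.frames[0]
    else:
        if not 0 <= ssfp_frame_index < n_baseline:
            raise ValidationError(
                "SSFP reference frame must be a pre-contrast baseline frame"
            )
        reference = perfusion.frames[ssfp_frame_index]

    body_mask = build_body_mask(reference, myo_mask, body_outline, lo_frac, hi_frac)
    fit, bias = fit_bias_surface(reference, myo_mask, body_mask, order=order)
    corrected = apply_scic(perfusion, bias)
    series, scale = baseline_normalize(corrected, myo_mask, n_baseline)
    return ScicResult(
        mode=mode,
        series=series,
        baseline_scale=scale,
        bias=bias,
        surface_fit=fit,
        body_mask=body_mask,
        reference=np.asarray(reference, dtype=np.float64).copy(),
        reference_corrected=reference / bias.field,
    )
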