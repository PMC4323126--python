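"""Core containers and NIfTI/JSON I/O for dynamic perfusion studies.

A perfusion study is a time-ordered stack of 2D short-axis frames
(:class:`DynamicSeries`), binary regions of interest (:class:`RoiMask`),
a multiplicative coil-gain estimate (:class:`BiasField`), contrast
concentration time courses (:class:`ConcentrationCurve`), pixel-wise flow
estimates (:class:`MBFMap`) and a six-sector angular segmentation of the
myocardium (:class:`SegmentLabels`).

Conventions
-----------
* Images are indexed ``(row=y, col=x)``, 0-based, with ``y`` increasing
  downward in the standard short-axis display (anterior up).
* Series arrays are stored ``(n_frames, ny, nx)`` in float64.
* On disk a series is a NIfTI volume with the frame index on the last
  axis, stored ``(x, y, t)``, plus a JSON sidecar carrying
  ``times_s``, ``pixel_spacing_mm`` ``[dy, dx]`` and ``series_role``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

SERIES_ROLES = ("perfusion", "aif", "pd")
MASK_LABELS = ("myocardium", "body", "blood_pool")

#: minimum pixel count for a mask used in surface fitting
MIN_FIT_PIXELS = 10


class ValidationError(ValueError):
    """An object violated one of its structural invariants."""


def _as_float_image(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValidationError(f"{name}: intensities must be finite")
    return out


@dataclass
class DynamicSeries:
    """A time-ordered stack of 2D frames with per-frame acquisition times.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Non-negative, finite image intensities (stored as float64).
    times_s : ndarray, shape (n_frames,)
        Strictly increasing acquisition time of each frame, seconds.
    pixel_spacing_mm : tuple of float
        ``(dy, dx)`` in millimetres.
    series_role : str
        One of ``perfusion``, ``aif``, ``pd``.
    """

    frames: np.ndarray
    times_s: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    series_role: str = "perfusion"

    def __post_init__(self) -> None:
        frames = _as_float_image(self.frames, "frames")
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValidationError(
                f"frames: expected (n_frames, ny, nx), got shape {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise ValidationError("frames: frame count must be >= 1")
        if np.any(frames < 0):
            raise ValidationError("frames: intensities must be >= 0")
        times = np.asarray(self.times_s, dtype=np.float64).ravel()
        if times.size != frames.shape[0]:
            raise ValidationError(
                f"times_s: length {times.size} does not match "
                f"{frames.shape[0]} frames"
            )
        if not np.all(np.isfinite(times)):
            raise ValidationError("times_s: times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("times_s: times not strictly increasing")
        spacing = tuple(float(v) for v in self.pixel_spacing_mm)
        if len(spacing) != 2 or any(v <= 0 for v in spacing):
            raise ValidationError("pixel_spacing_mm: expected two positive values")
        if self.series_role not in SERIES_ROLES:
            raise ValidationError(
                f"series_role: {self.series_role!r} not in {SERIES_ROLES}"
            )
        self.frames = frames
        self.times_s = times
        self.pixel_spacing_mm = spacing

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray) -> "DynamicSeries":
        """Return a copy with new pixel data, preserving timing/metadata."""
        return DynamicSeries(
            frames=frames,
            times_s=self.times_s.copy(),
            pixel_spacing_mm=self.pixel_spacing_mm,
            series_role=self.series_role,
        )


@dataclass
class RoiMask:
    """A binary 2D region of interest with a semantic label."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise ValidationError(f"mask: expected 2D, got shape {mask.shape}")
        self.mask = mask != 0
        if self.label not in MASK_LABELS:
            raise ValidationError(f"label: {self.label!r} not in {MASK_LABELS}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_fit_pixels(self) -> None:
        """Raise unless the mask is large enough to anchor a surface fit."""
        if self.n_pixels < MIN_FIT_PIXELS:
            raise ValidationError(
                f"mask '{self.label}' has < {MIN_FIT_PIXELS} pixels "
                f"({self.n_pixels}); too small for surface fitting"
            )


@dataclass
class BiasField:
    """A smooth, strictly positive multiplicative gain estimate.

    The field is normalized to unit mean over the mask named by
    ``normalization_mask_label`` (the myocardium, by default), so that
    dividing a series by the field does not rescale mean myocardial signal.
    """

    field: np.ndarray
    normalization_mask_label: str = "myocardium"

    def __post_init__(self) -> None:
        f = _as_float_image(self.field, "field")
        if f.ndim != 2:
            raise ValidationError(f"field: expected 2D, got shape {f.shape}")
        if np.any(f <= 0):
            raise ValidationError("field: bias field must be strictly positive")
        if self.normalization_mask_label not in MASK_LABELS:
            raise ValidationError(
                f"normalization_mask_label: {self.normalization_mask_label!r} "
                f"not in {MASK_LABELS}"
            )
        self.field = f

    @classmethod
    def from_surface(cls, surface: np.ndarray, mask: RoiMask) -> "BiasField":
        """Normalize a fitted surface to unit mean over ``mask`` and wrap it."""
        surface = np.asarray(surface, dtype=np.float64)
        mean = float(surface[mask.mask].mean())
        if mean <= 0:
            raise ValidationError("surface has non-positive mean over mask")
        return cls(field=surface / mean, normalization_mask_label=mask.label)

    def check_normalized(self, mask: RoiMask, tol: float = 1e-9) -> None:
        mean = float(self.field[mask.mask].mean())
        if abs(mean - 1.0) > tol:
            raise ValidationError(
                f"bias field mean over {mask.label} is {mean}, expected 1"
            )


@dataclass
class ConcentrationCurve:
    """A 1D contrast-concentration time course (AIF or tissue).

    Values are in mmol/L or any consistent linear rescaling of it; what
    matters downstream is that AIF and tissue curves share one scale.
    """

    values: np.ndarray
    times_s: np.ndarray
    foot_index: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        times = np.asarray(self.times_s, dtype=np.float64).ravel()
        if values.size != times.size:
            raise ValidationError(
                f"values length {values.size} != times length {times.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("values: must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("times_s: times not strictly increasing")
        if self.foot_index is not None:
            fi = int(self.foot_index)
            if not 0 <= fi < values.size:
                raise ValidationError(f"foot_index {fi} out of range")
            self.foot_index = fi
        self.values = values
        self.times_s = times

    def __len__(self) -> int:
        return self.values.size

    def scaled(self, factor: float) -> "ConcentrationCurve":
        return ConcentrationCurve(
            self.values * factor, self.times_s.copy(), self.foot_index
        )


@dataclass
class MBFMap:
    """Pixel-wise myocardial blood flow estimates over a myocardial mask.

    ``mbf`` is in mL/min/g and is NaN exactly off the mask; ``fit_rss`` and
    ``converged`` carry per-pixel fit diagnostics.
    """

    mbf: np.ndarray
    fit_rss: np.ndarray
    converged: np.ndarray
    mask: RoiMask

    def __post_init__(self) -> None:
        mbf = np.asarray(self.mbf, dtype=np.float64)
        rss = np.asarray(self.fit_rss, dtype=np.float64)
        conv = np.asarray(self.converged, dtype=bool)
        m = self.mask.mask
        if not (mbf.shape == rss.shape == conv.shape == m.shape):
            raise ValidationError("MBFMap: component shapes differ")
        if not np.all(np.isnan(mbf[~m])):
            raise ValidationError("MBFMap: mbf must be NaN outside the mask")
        if np.any(np.isnan(mbf[m])):
            raise ValidationError("MBFMap: mbf must be defined on the mask")
        if np.any(mbf[m & conv] < 0):
            raise ValidationError("MBFMap: mbf must be >= 0 where converged")
        self.mbf, self.fit_rss, self.converged = mbf, rss, conv

    @property
    def converged_values(self) -> np.ndarray:
        """MBF values at converged myocardial pixels."""
        return self.mbf[self.mask.mask & self.converged]


@dataclass
class SegmentLabels:
    """Six 60-degree angular sectors over the myocardium (AHA mid-slice).

    Labels run 1..6 clockwise from the anterior RV insertion angle in the
    order anterior, anterolateral, inferolateral, inferior, inferoseptum,
    anteroseptum; 0 marks pixels outside the myocardium.
    """

    labels: np.ndarray
    rv_insertion_angle_deg: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValidationError("labels: expected 2D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("labels: expected integer image")
        vals = np.unique(labels)
        if np.any((vals < 0) | (vals > 6)):
            raise ValidationError("labels: values must lie in 0..6")
        self.labels = labels.astype(np.int32)
        self.rv_insertion_angle_deg = float(self.rv_insertion_angle_deg)


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------

_SIDE_CAR_KEYS = ("times_s", "pixel_spacing_mm", "series_role")


def sidecar_path(path: str | Path) -> Path:
    """Return the JSON sidecar path adjacent to a NIfTI file."""
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return p.with_name(name + ".json")


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    dy, dx = spacing
    return np.diag([dx, dy, 1.0, 1.0])


def write_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write a series as NIfTI (x, y, t) plus a JSON sidecar.

    ``read_series(write_series(s))`` is the identity on values, times and
    spacing (within float representation).
    """
    path = Path(path)
    # frames (t, y, x) -> (x, y, t) so the frame index is the file's last axis
    data = np.transpose(series.frames, (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(series.pixel_spacing_mm))
    nib.save(img, str(path))
    meta = {
        "times_s": [float(t) for t in series.times_s],
        "pixel_spacing_mm": [float(v) for v in series.pixel_spacing_mm],
        "series_role": series.series_role,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_series(path: str | Path, sidecar: str | Path | None = None) -> DynamicSeries:
    """Read a NIfTI volume plus JSON sidecar into a validated DynamicSeries.

    The volume may be (x, y, t) or a single 2D (x, y) frame.
    """
    path = Path(path)
    sc = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sc.exists():
        raise ValidationError(f"missing sidecar file: {sc}")
    meta = json.loads(sc.read_text())
    for key in _SIDE_CAR_KEYS:
        if key not in meta:
            raise ValidationError(f"sidecar {sc} missing key '{key}'")
    data = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected 2D or 3D volume, got {data.ndim}D")
    frames = np.transpose(data, (2, 1, 0))
    return DynamicSeries(
        frames=frames,
        times_s=np.asarray(meta["times_s"], dtype=np.float64),
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        series_role=meta["series_role"],
    )


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    data = np.transpose(mask.mask.astype(np.uint8), (1, 0))
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    return path


def read_mask(
    path: str | Path,
    label: str,
    reference: DynamicSeries | None = None,
) -> RoiMask:
    """Read a binary mask; any nonzero value is treated as 1.

    If ``reference`` is given, the mask shape must match its frame shape.
    """
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 2:
        raise ValidationError(f"{path}: expected 2D mask, got shape {data.shape}")
    mask = RoiMask(mask=np.transpose(data, (1, 0)) != 0, label=label)
    if reference is not None and mask.mask.shape != reference.frame_shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} does not match reference "
            f"frame shape {reference.frame_shape}"
        )
    return mask


def write_curve_csv(curve: ConcentrationCurve, path: str | Path) -> Path:
    """Export a curve as two-column CSV (time_s, value)."""
    path = Path(path)
    lines = ["time_s,value"]
    lines += [f"{t!r},{v!r}" for t, v in zip(curve.times_s, curve.values)]
    path.write_text("\n".join(lines) + "\n")
    return path
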