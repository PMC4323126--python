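"""Regional comparison statistics for SCIC evaluation.

Implements the six-sector AHA mid-ventricular segmentation anchored at the
anterior RV insertion point, the coronary-territory grouping (anterior +
anteroseptum -> LAD, anterolateral + inferolateral -> LCX, inferior +
inferoseptum -> RCA), and the summary statistics used to compare
correction modes: myocardial signal CoV, MBF spatial heterogeneity,
septal-vs-lateral and remote-vs-ischaemic differences, and paired t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .core import MBFMap, RoiMask, SegmentLabels, ValidationError

SEGMENT_NAMES = {
    1: "anterior",
    2: "anterolateral",
    3: "inferolateral",
    4: "inferior",
    5: "inferoseptum",
    6: "anteroseptum",
}

#: AHA coronary territory of each mid-ventricular segment
SEGMENT_TERRITORY = {1: "LAD", 2: "LCX", 3: "LCX", 4: "RCA", 5: "RCA", 6: "LAD"}

TERRITORIES = ("LAD", "LCX", "RCA")


@dataclass(frozen=True)
class TerritoryAssignment:
    """Which coronary territories are diseased (stenosed).

    A strict, nonempty subset of {LAD, LCX, RCA}: triple-vessel disease
    leaves no remote territory and is rejected.
    """

    diseased: frozenset

    def __post_init__(self) -> None:
        diseased = frozenset(self.diseased)
        unknown = diseased - set(TERRITORIES)
        if unknown:
            raise ValidationError(f"unknown territories: {sorted(unknown)}")
        if not diseased:
            raise ValidationError("diseased set must be nonempty")
        if diseased == set(TERRITORIES):
            raise ValidationError("no remote territory: all territories diseased")
        object.__setattr__(self, "diseased", diseased)

    @property
    def remote(self) -> frozenset:
        return frozenset(TERRITORIES) - self.diseased


def pixel_angles_deg(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Angle of each pixel about ``center``, degrees clockwise from anterior.

    Anterior is 'up' in the displayed image (decreasing row index); angles
    increase clockwise in the standard short-axis display.
    """
    cy, cx = center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.degrees(np.arctan2(xx - cx, -(yy - cy))) % 360.0


def sectorize(
    myo_mask: RoiMask,
    center: tuple[float, float],
    rv_insertion_angle_deg: float,
) -> SegmentLabels:
    """Assign each myocardial pixel to one of six 60-degree sectors.

    Sector 1 (anterior) starts at the anterior RV insertion angle and the
    labels proceed clockwise: anterior, anterolateral, inferolateral,
    inferior, inferoseptum, anteroseptum.
    """
    if myo_mask.n_pixels == 0:
        raise ValidationError("sectorize: empty myocardial mask")
    angles = pixel_angles_deg(myo_mask.mask.shape, center)
    rel = (angles - rv_insertion_angle_deg) % 360.0
    labels = (rel // 60.0).astype(np.int32) + 1
    labels[~myo_mask.mask] = 0
    counts = np.bincount(labels.ravel(), minlength=7)[1:]
    if np.any(counts == 0):
        empty = [SEGMENT_NAMES[i + 1] for i in range(6) if counts[i] == 0]
        raise ValidationError(f"degenerate geometry: empty sectors {empty}")
    return SegmentLabels(labels=labels, rv_insertion_angle_deg=rv_insertion_angle_deg)


def cov_si(image: np.ndarray, myo_mask: RoiMask) -> float:
    """Coefficient of variation of myocardial signal intensity, percent.

    100 x sample SD / mean over the mask.
    """
    values = np.asarray(image, dtype=np.float64)[myo_mask.mask]
    if values.size < 2:
        raise ValidationError("cov_si: need >= 2 myocardial pixels")
    mean = float(values.mean())
    if mean <= 0:
        raise ValidationError("cov_si: non-positive mean signal")
    return 100.0 * float(values.std(ddof=1)) / mean


def heterogeneity(mbf: MBFMap) -> float:
    """MBF spatial heterogeneity: 100 x sample SD / mean of pixel MBF.

    Computed over converged myocardial pixels only.
    """
    values = mbf.converged_values
    if values.size < 2:
        raise ValidationError("heterogeneity: need >= 2 converged pixels")
    mean = float(values.mean())
    if mean <= 0:
        raise ValidationError("heterogeneity: non-positive mean MBF")
    return 100.0 * float(values.std(ddof=1)) / mean


def sector_stats(mbf: MBFMap, labels: SegmentLabels) -> np.ndarray:
    """Mean MBF of converged pixels per sector; entry i is sector i+1."""
    ok = mbf.mask.mask & mbf.converged
    means = np.empty(6)
    for sec in range(1, 7):
        sel = ok & (labels.labels == sec)
        if not np.any(sel):
            raise ValidationError(
                f"sector {sec} ({SEGMENT_NAMES[sec]}) has no converged pixels"
            )
        means[sec - 1] = mbf.mbf[sel].mean()
    return means


def septal_lateral_difference(sector_means: np.ndarray) -> float:
    """Septal minus lateral wall MBF.

    mean(anteroseptum, inferoseptum) - mean(anterolateral, inferolateral).
    """
    m = np.asarray(sector_means, dtype=np.float64)
    if m.shape != (6,):
        raise ValidationError("expected 6 sector means")
    septal = 0.5 * (m[5] + m[4])       # anteroseptum, inferoseptum
    lateral = 0.5 * (m[1] + m[2])      # anterolateral, inferolateral
    return float(septal - lateral)


def territory_means(sector_means: np.ndarray) -> dict[str, float]:
    """Mean MBF per coronary territory (unweighted mean of its sectors)."""
    m = np.asarray(sector_means, dtype=np.float64)
    out = {}
    for terr in TERRITORIES:
        secs = [s for s, t in SEGMENT_TERRITORY.items() if t == terr]
        out[terr] = float(np.mean([m[s - 1] for s in secs]))
    return out


def remote_ischaemic_difference(
    sector_means: np.ndarray,
    assignment: TerritoryAssignment,
) -> tuple[float, float, float]:
    """(remote mean, ischaemic mean, remote - ischaemic) MBF.

    Each group mean is the unweighted mean over the sectors belonging to
    its territories.
    """
    m = np.asarray(sector_means, dtype=np.float64)
    isch = [m[s - 1] for s, t in SEGMENT_TERRITORY.items() if t in assignment.diseased]
    remote = [m[s - 1] for s, t in SEGMENT_TERRITORY.items() if t in assignment.remote]
    isch_mean = float(np.mean(isch))
    remote_mean = float(np.mean(remote))
    return remote_mean, isch_mean, remote_mean - isch_mean


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError("paired_t_test: unequal sample lengths")
    n = x.size
    if n < 2:
        raise ValidationError("paired_t_test: need n >= 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("degenerate pairs: zero variance of differences")
    t = float(d.mean()) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


# ---------------------------------------------------------------------------
# Study-level report
# ---------------------------------------------------------------------------


@dataclass
class ModeResult:
    """Summary statistics of one SCIC mode applied to one study."""

    mode: str
    reference_cov_pct: float
    heterogeneity_pct: float
    sector_means: list
    septal_lateral_diff: float
    remote_mbf: float | None = None
    ischaemic_mbf: float | None = None
    remote_ischaemic_diff: float | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "reference_cov_pct": self.reference_cov_pct,
            "heterogeneity_pct": self.heterogeneity_pct,
            "sector_means": [float(v) for v in self.sector_means],
            "septal_lateral_diff": self.septal_lateral_diff,
            "remote_mbf": self.remote_mbf,
            "ischaemic_mbf": self.ischaemic_mbf,
            "remote_ischaemic_diff": self.remote_ischaemic_diff,
        }


@dataclass
class ComparisonReport:
    """Per-mode statistics for one study, with optional paired contrasts.

    Paired t-tests need replicate studies (one pair member per subject or
    phantom replicate), so for a single study ``paired_tests`` is empty;
    see :func:`cohort_paired_tests`.
    """

    modes: dict
    notes: list = field(default_factory=list)
    paired_tests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "modes": {k: v.to_dict() for k, v in self.modes.items()},
            "notes": list(self.notes),
            "paired_tests": self.paired_tests,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        modes = {k: ModeResult(**v) for k, v in d["modes"].items()}
        return cls(modes=modes, notes=list(d.get("notes", [])),
                   paired_tests=dict(d.get("paired_tests", {})))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ComparisonReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


def build_report(mode_results: dict) -> ComparisonReport:
    """Assemble per-mode results into a study report.

    ``mode_results`` maps mode name -> :class:`ModeResult`; at least one
    mode is required.  Contrasts needing two modes are annotated when a
    mode is missing rather than silently dropped.
    """
    if not mode_results:
        raise ValidationError("build_report: no modes supplied")
    notes = []
    if len(mode_results) < 2:
        notes.append(
            "single mode only: paired contrasts between correction modes "
            "require at least two modes"
        )
    return ComparisonReport(modes=dict(mode_results), notes=notes)


def cohort_paired_tests(
    reports: list,
    field_name: str,
    mode_a: str,
    mode_b: str,
) -> dict:
    """Paired t-test of one statistic between two modes across replicates."""
    x = [getattr(r.modes[mode_a], field_name) for r in reports]
    y = [getattr(r.modes[mode_b], field_name) for r in reports]
    t, df, p = paired_t_test(x, y)
    return {
        "field": field_name,
        "modes": [mode_a, mode_b],
        "mean_a": float(np.mean(x)),
        "mean_b": float(np.mean(y)),
        "t": t,
        "df": df,
        "p": p,
    }
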