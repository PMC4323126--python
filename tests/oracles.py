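"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the implementation:
plain double loops, truncated-SVD deconvolution, and brute-force pixel
scans.  They must stay independent of the code paths they validate.
"""

from __future__ import annotations

import numpy as np


def double_loop_convolve(a, r, dt: float) -> np.ndarray:
    """Trapezoidal causal convolution as an explicit double sum."""
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    n = a.size
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for m in range(i + 1):
            w = 0.5 if (m == 0 or m == i) else 1.0
            acc += w * a[m] * r[i - m]
        out[i] = dt * acc if i > 0 else 0.0
    return out


def tsvd_deconvolve(aif, tissue, dt: float, rel_cutoff: float = 0.1) -> np.ndarray:
    """Model-independent impulse response by truncated-SVD deconvolution.

    Builds the lower-triangular convolution matrix (rectangle rule),
    discards singular values below ``rel_cutoff`` of the largest, and
    returns the regularized impulse response.  Used as a cross-check of
    the model-constrained estimate's initial height.
    """
    a = np.asarray(aif, dtype=float)
    n = a.size
    A = np.zeros((n, n))
    for i in range(n):
        A[i, : i + 1] = a[i::-1] * dt
    U, s, Vt = np.linalg.svd(A)
    keep = s >= rel_cutoff * s[0]
    inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return Vt.T @ (inv * (U.T @ np.asarray(tissue, dtype=float)))


def brute_force_sectors(mask, center, rv_angle_deg: float) -> np.ndarray:
    """Sector labels by an explicit per-pixel angle loop."""
    cy, cx = center
    labels = np.zeros(mask.shape, dtype=int)
    for iy in range(mask.shape[0]):
        for ix in range(mask.shape[1]):
            if not mask[iy, ix]:
                continue
            ang = np.degrees(np.arctan2(ix - cx, -(iy - cy))) % 360.0
            rel = (ang - rv_angle_deg) % 360.0
            labels[iy, ix] = int(rel // 60.0) + 1
    return labels


def band_mask_loop(reference, myo_mask, outline, lo_frac, hi_frac) -> np.ndarray:
    """Body-band mask by an explicit pixel loop."""
    m = float(np.median(reference[myo_mask]))
    out = np.zeros(reference.shape, dtype=bool)
    for iy in range(reference.shape[0]):
        for ix in range(reference.shape[1]):
            v = reference[iy, ix]
            out[iy, ix] = (
                outline[iy, ix]
                and not myo_mask[iy, ix]
                and lo_frac * m <= v <= hi_frac * m
            )
    return out
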