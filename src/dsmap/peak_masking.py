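"""Bragg-peak masking: strong-pixel search, ellipsoidal Gaussian fit, masks.

Pixels contaminated by Bragg diffraction are excluded before integration.
Strong pixels (counts strictly above a threshold, default 20 photons) are
mapped to fractional Miller offsets Δhkl from the nearest integer node
(each component wrapped to [−0.5, 0.5)) and an ellipsoidal Gaussian is
fitted to the point cloud.  A mask is then applied at every predicted
Bragg-peak location — every integer node passing the centering reflection
condition — regardless of intensity, by thresholding the Mahalanobis
distance at a sigma cutoff (default 3).  Strong pixels not covered by any
ellipsoid are flagged as outliers (dead pixels, salt crystals) and also
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .grid_symmetry import MillerGrid, centering_allowed, voxel_center

__all__ = [
    "PeakShape",
    "PeakMask",
    "find_strong_pixels",
    "fit_peak_shape",
    "build_peak_mask",
    "flag_outliers",
    "wrap_delta_hkl",
]

MIN_FIT_POINTS = 10


def wrap_delta_hkl(hkl_frac) -> np.ndarray:
    """Offset from the nearest integer node, each component in [−0.5, 0.5)."""
    arr = np.asarray(hkl_frac, dtype=float)
    return (arr + 0.5) % 1.0 - 0.5


@dataclass(frozen=True)
class PeakShape:
    """Ellipsoidal Gaussian peak shape in fractional-hkl offset space."""

    mean: np.ndarray
    covariance: np.ndarray
    n_points: int

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric 3x3")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")

    def mahalanobis_sq(self, delta) -> np.ndarray:
        """Squared Mahalanobis distance of Δhkl offsets from the peak."""
        d = np.atleast_2d(np.asarray(delta, dtype=float)) - np.asarray(self.mean)
        cho = linalg.cho_factor(np.asarray(self.covariance))
        sol = linalg.cho_solve(cho, d.T)
        out = np.einsum("ni,in->n", d, sol)
        return float(out[0]) if np.asarray(delta).ndim == 1 else out


def find_strong_pixels(images, threshold: float, mask=None):
    """Pixels with counts strictly greater than ``threshold``.

    ``images`` is a (frames, x, y) stack; ``mask`` (True = bad) of shape
    (x, y) or the stack shape is excluded.  Returns arrays
    ``(frame, x, y, count)``; all empty if nothing exceeds the threshold.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    stack = np.asarray(images)
    strong = stack > threshold
    if mask is not None:
        strong &= ~np.broadcast_to(np.asarray(mask, dtype=bool), stack.shape)
    frame, x, y = np.nonzero(strong)
    return frame, x, y, stack[frame, x, y]


def fit_peak_shape(delta_hkl_points) -> PeakShape:
    """Fit mean and sample covariance to a cloud of Δhkl offsets.

    Points are wrapped to [−0.5, 0.5) per component first, so peaks falling
    near voxel-cell boundaries are handled.  Requires at least
    ``MIN_FIT_POINTS`` points and a full-rank covariance.
    """
    pts = wrap_delta_hkl(np.atleast_2d(np.asarray(delta_hkl_points, dtype=float)))
    if len(pts) < MIN_FIT_POINTS:
        raise ValueError(
            f"need at least {MIN_FIT_POINTS} strong pixels to fit the peak "
            f"shape, got {len(pts)}"
        )
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = 0.5 * (cov + cov.T)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 1e-12 * max(eig.max(), 1e-30):
        raise ValueError("rank-deficient peak-shape covariance")
    return PeakShape(mean=mean, covariance=cov, n_points=len(pts))


@dataclass(frozen=True)
class PeakMask:
    """Ellipsoidal Bragg mask: thresholded Mahalanobis distance."""

    grid: MillerGrid
    shape: PeakShape
    n_sigma: float = 3.0

    def __post_init__(self):
        if not self.n_sigma > 0:
            raise ValueError("n_sigma must be positive")

    def contains_hkl(self, hkl_frac) -> np.ndarray:
        """True where a fractional-hkl location falls inside the ellipsoid
        of a predicted (centering-allowed) Bragg node."""
        arr = np.atleast_2d(np.asarray(hkl_frac, dtype=float))
        node = np.rint(arr).astype(np.int64)
        delta = arr - node
        inside = self.shape.mahalanobis_sq(delta) <= self.n_sigma**2
        predicted = centering_allowed(node, self.grid.centering)
        out = inside & predicted
        return bool(out[0]) if np.asarray(hkl_frac).ndim == 1 else out

    def contains_voxel(self, v) -> np.ndarray:
        """Voxel predicate: evaluated at the voxel center."""
        return self.contains_hkl(voxel_center(v, self.grid))


def build_peak_mask(grid: MillerGrid, shape: PeakShape, n_sigma: float = 3.0) -> PeakMask:
    return PeakMask(grid=grid, shape=shape, n_sigma=n_sigma)


def flag_outliers(strong_hkl_frac, mask: PeakMask) -> np.ndarray:
    """Strong pixels outside every Bragg ellipsoid; boolean per pixel."""
    arr = np.atleast_2d(np.asarray(strong_hkl_frac, dtype=float))
    if arr.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    out = ~mask.contains_hkl(arr)
    return out
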