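"""Background maps and per-observation intensity/uncertainty corrections.

Background scattering (air, capillary, loop) is measured with the crystal
translated out of the beam, binned down over frames and pixels to reduce
Poisson noise, and interpolated at the scan coordinates of each observation.
Corrected intensities follow

    I     = (n/Δt − r_bg) / (ΔΩ · E · A · P)
    σ(I)  = sqrt(n)/Δt   / (ΔΩ · E · A · P)

where n is the accumulated photon count, Δt the cumulative exposure time,
r_bg the interpolated background rate (photons/s), ΔΩ the solid angle per
pixel, E the detector quantum efficiency, A the air transmission and P the
polarization factor.  The Poisson error of the (heavily binned) background
is neglected.  Zero-count observations get σ = 0 and are excluded from
weighted merging downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackgroundMap",
    "CorrectionFactors",
    "bin_image_stack",
    "background_rate",
    "correct_observation",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Multiplicative geometric corrections per observation."""

    solid_angle: float = 1.0
    efficiency: float = 1.0
    transmission: float = 1.0
    polarization: float = 1.0

    def __post_init__(self):
        for name in ("solid_angle", "efficiency", "transmission", "polarization"):
            val = np.asarray(getattr(self, name))
            if not np.all(val > 0):
                raise ValueError(f"correction factor {name} must be positive")

    @property
    def product(self):
        return (
            np.asarray(self.solid_angle)
            * np.asarray(self.efficiency)
            * np.asarray(self.transmission)
            * np.asarray(self.polarization)
        )


@dataclass
class BackgroundMap:
    """Binned background rate map on a coarse (frame, x, y) grid.

    ``rate`` is photons·pixel⁻¹·s⁻¹; ``valid`` marks bins that contained at
    least one unmasked pixel.  ``centers`` holds the bin-center coordinates
    (original frame / pixel indices) along each axis.
    """

    rate: np.ndarray
    valid: np.ndarray
    bin_sizes: tuple[int, int, int]
    centers: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self):
        if self.rate.ndim != 3:
            raise ValueError("rate must be a 3-D array")
        if np.any(self.rate[self.valid] < 0):
            raise ValueError("background rates must be non-negative")


def _bin_edges(extent: int, size: int) -> np.ndarray:
    edges = np.arange(0, extent, size)
    return edges


def _bin_sum(arr: np.ndarray, size: int, axis: int) -> np.ndarray:
    if size == 1:
        return arr
    idx = _bin_edges(arr.shape[axis], size)
    return np.add.reduceat(arr, idx, axis=axis)


def bin_image_stack(
    stack,
    exposure_per_frame: float,
    frame_bin: int = 1,
    pixel_bin: int = 1,
    mask=None,
) -> BackgroundMap:
    """Bin a (frames, x, y) photon-count stack into a BackgroundMap.

    Each cell holds the mean rate (counts / exposure) over unmasked pixels
    in the bin; partial bins at the array edges are retained (ceiling
    division), so e.g. 2463 pixels binned by 20 give 124 bins.  ``mask`` is
    an optional boolean array (True = masked/bad) of shape (x, y) or the
    full stack shape.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, x, y)")
    if frame_bin < 1 or pixel_bin < 1:
        raise ValueError("bin sizes must be >= 1")
    if exposure_per_frame <= 0:
        raise ValueError("exposure_per_frame must be positive")
    if mask is None:
        good = np.ones(stack.shape, dtype=float)
    else:
        mask = np.asarray(mask, dtype=bool)
        good = np.broadcast_to(~mask, stack.shape).astype(float)

    counts = stack * good
    sizes = (frame_bin, pixel_bin, pixel_bin)
    for axis, size in enumerate(sizes):
        counts = _bin_sum(counts, size, axis)
        good = _bin_sum(good, size, axis)

    valid = good > 0
    if not valid.any():
        raise ValueError("every bin is fully masked")
    rate = np.zeros_like(counts)
    rate[valid] = counts[valid] / (good[valid] * exposure_per_frame)

    centers = []
    for axis, size in enumerate(sizes):
        starts = _bin_edges(stack.shape[axis], size)
        stops = np.minimum(starts + size, stack.shape[axis])
        centers.append((starts + stops - 1) / 2.0)
    return BackgroundMap(rate, valid, sizes, tuple(centers))


def background_rate(bmap: BackgroundMap, frame, x, y) -> np.ndarray:
    """Multilinear interpolation of the background map at scan coordinates.

    Queries outside the bin-center lattice clamp to the edge values.
    Invalid (fully masked) cells are excluded by renormalizing the
    interpolation weights; if every neighboring cell is invalid the result
    is NaN, flagging the observation.
    """
    coords = [np.atleast_1d(np.asarray(c, dtype=float)) for c in (frame, x, y)]
    n = len(coords[0])
    lo = np.empty((3, n), dtype=np.int64)
    t = np.empty((3, n))
    for d, (c, centers) in enumerate(zip(coords, bmap.centers)):
        ax = np.asarray(centers, dtype=float)
        if ax.size == 1:
            lo[d] = 0
            t[d] = 0.0
            continue
        cc = np.clip(c, ax[0], ax[-1])
        i0 = np.clip(np.searchsorted(ax, cc, side="right") - 1, 0, ax.size - 2)
        lo[d] = i0
        t[d] = (cc - ax[i0]) / (ax[i0 + 1] - ax[i0])

    num = np.zeros(n)
    den = np.zeros(n)
    shape = bmap.rate.shape
    for bits in range(8):
        b = [(bits >> d) & 1 for d in range(3)]
        w = np.ones(n)
        idx = []
        for d in range(3):
            w = w * (t[d] if b[d] else 1.0 - t[d])
            idx.append(np.minimum(lo[d] + b[d], shape[d] - 1))
        cell_valid = bmap.valid[idx[0], idx[1], idx[2]]
        w = w * cell_valid
        num += w * bmap.rate[idx[0], idx[1], idx[2]]
        den += w
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if np.ndim(frame) == 0 and np.ndim(x) == 0 and np.ndim(y) == 0:
        return float(out[0])
    return out


def correct_observation(n, dt, r_bg=0.0, factors: CorrectionFactors | None = None):
    """Corrected intensity and standard error for accumulated counts.

    Returns ``(I, sigma)``.  Observations with n = 0 get sigma = 0; callers
    treat sigma <= 0 as unusable for inverse-variance weighting.
    """
    n_arr = np.asarray(n, dtype=float)
    dt_arr = np.asarray(dt, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("photon counts must be non-negative")
    if not np.all(dt_arr > 0):
        raise ValueError("cumulative exposure must be positive")
    if factors is None:
        factors = CorrectionFactors()
    f = np.asarray(factors.product, dtype=float)
    if not np.all(f > 0):
        raise ValueError("correction factors must be positive")
    intensity = (n_arr / dt_arr - np.asarray(r_bg, dtype=float)) / f
    sigma = np.sqrt(n_arr) / dt_arr / f
    return intensity, sigma
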