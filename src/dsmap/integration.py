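"""Accumulate masked per-pixel photon counts onto the voxel grid.

Each unmasked pixel carries fractional Miller indices (computed upstream by
the diffraction geometry, or by the simulator) and is assigned to the
nearest voxel.  For every (voxel, sweep) the accumulator tracks the total
photon count, the number of contributing pixels and the unweighted mean
scan coordinates (rotation angle φ and detector position x, y).  The
accumulation is an associative, commutative merge over chunks of the pixel
stream, so the result is independent of chunking and worker count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .grid_symmetry import (
    MillerGrid,
    map_to_asu,
    pack_voxels,
    s_magnitude,
    unpack_voxels,
    voxel_center,
    voxel_of,
)

__all__ = ["integrate", "accumulate_chunk", "combine_partials", "finalize_table"]

OBS_COLUMNS = [
    "i", "j", "k", "key", "asu_key", "friedel",
    "n", "n_pixels", "phi", "x", "y", "s", "dt", "batch",
]


def accumulate_chunk(pixels: pd.DataFrame, grid: MillerGrid) -> pd.DataFrame:
    """Partial accumulator (per-voxel sums) for one chunk of pixels."""
    counts = pixels["count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("pixel with negative count")
    hkl = pixels[["h", "k", "l"]].to_numpy(dtype=float)
    vox = voxel_of(hkl, grid)
    key = pack_voxels(vox)
    part = pd.DataFrame(
        {
            "key": key,
            "n": counts.astype(np.int64),
            "n_pixels": np.ones(len(key), dtype=np.int64),
            "sum_phi": pixels["phi"].to_numpy(dtype=float),
            "sum_x": pixels["x"].to_numpy(dtype=float),
            "sum_y": pixels["y"].to_numpy(dtype=float),
        }
    )
    return part.groupby("key", sort=True).sum().reset_index()


def combine_partials(partials) -> pd.DataFrame:
    """Merge partial accumulators (associative/commutative sum per voxel)."""
    parts = [p for p in partials if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=["key", "n", "n_pixels", "sum_phi", "sum_x", "sum_y"]
        )
    return pd.concat(parts).groupby("key", sort=True).sum().reset_index()


def finalize_table(
    acc: pd.DataFrame, grid: MillerGrid, exposure_per_image: float, batch
) -> pd.DataFrame:
    """Turn a combined accumulator into an observation table."""
    vox = unpack_voxels(acc["key"].to_numpy())
    vox = np.atleast_2d(vox)
    if len(acc) == 0:
        return pd.DataFrame(columns=OBS_COLUMNS)
    asu, _, friedel = map_to_asu(vox, grid)
    n_pix = acc["n_pixels"].to_numpy()
    table = pd.DataFrame(
        {
            "i": vox[:, 0],
            "j": vox[:, 1],
            "k": vox[:, 2],
            "key": acc["key"].to_numpy(),
            "asu_key": pack_voxels(asu),
            "friedel": friedel,
            "n": acc["n"].to_numpy(),
            "n_pixels": n_pix,
            "phi": acc["sum_phi"].to_numpy() / n_pix,
            "x": acc["sum_x"].to_numpy() / n_pix,
            "y": acc["sum_y"].to_numpy() / n_pix,
            "s": s_magnitude(voxel_center(vox, grid), grid.cell),
            "dt": n_pix * float(exposure_per_image),
            "batch": batch,
        }
    )
    return table


def integrate(
    pixels: pd.DataFrame,
    grid: MillerGrid,
    exposure_per_image: float,
    batch=0,
    peak_mask=None,
    exclude=None,
    n_chunks: int = 1,
    nproc: int = 1,
) -> pd.DataFrame:
    """Integrate a pixel stream into an observation table.

    ``pixels`` needs columns ``phi, x, y, count, h, k, l`` (h, k, l are
    fractional Miller indices).  ``peak_mask`` is an optional
    :class:`~dsmap.peak_masking.PeakMask`; ``exclude`` an optional boolean
    array (True = drop, e.g. flagged outlier pixels).  ``n_chunks`` and
    ``nproc`` control the partitioning/parallelism of the accumulation and
    must not change the result (counts are exact integer sums; coordinate
    means agree to floating-point rounding).
    """
    if exposure_per_image <= 0:
        raise ValueError("exposure_per_image must be positive")
    keep = np.ones(len(pixels), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if peak_mask is not None:
        hkl = pixels[["h", "k", "l"]].to_numpy(dtype=float)
        keep &= ~np.atleast_1d(peak_mask.contains_hkl(hkl))
    use = pixels.loc[keep]

    n_chunks = max(int(n_chunks), 1)
    bounds = np.linspace(0, len(use), n_chunks + 1).astype(int)
    chunks = [use.iloc[bounds[c]: bounds[c + 1]] for c in range(n_chunks)]
    if nproc > 1 and n_chunks > 1:
        partials = Parallel(n_jobs=nproc, prefer="processes")(
            delayed(accumulate_chunk)(chunk, grid) for chunk in chunks
        )
    else:
        partials = [accumulate_chunk(chunk, grid) for chunk in chunks]
    acc = combine_partials(partials)
    return finalize_table(acc, grid, exposure_per_image, batch)
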