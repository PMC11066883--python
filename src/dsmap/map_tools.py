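"""Symmetry expansion into 3-D reciprocal-space maps and isotropic subtraction.

Merged intensities live on the asymmetric unit; for visualization they are
expanded by the Laue group into a dense 3-D voxel array.  Unobserved voxels
carry NaN (a dedicated missing marker, never zero, so plots can distinguish
"not measured" from "zero intensity").  To reveal the weak variational
signal, the isotropic component — the mean non-halo intensity per
resolution shell, linearly interpolated in s — can be subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_symmetry import MillerGrid, map_to_asu, pack_voxels
from .merge_stats import ShellScheme, halo_partition

__all__ = ["ReciprocalMap", "expand_map", "subtract_isotropic", "isotropic_curve"]

MISSING = np.nan


@dataclass
class ReciprocalMap:
    """Dense voxel-index array with bounds and a missing-value marker."""

    data: np.ndarray
    bounds: tuple  # ((imin, imax), (jmin, jmax), (kmin, kmax)), inclusive
    grid: MillerGrid

    def slice_l(self, k_index: int) -> np.ndarray:
        """Plane at a fixed third voxel index."""
        (imin, _), (jmin, _), (kmin, _) = self.bounds
        return self.data[:, :, k_index - kmin]

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fractional-hkl coordinates of the voxel centers along each axis."""
        sub = self.grid.subdivision
        return tuple(
            np.arange(lo, hi + 1) / sub[d] for d, (lo, hi) in enumerate(self.bounds)
        )


def expand_map(merged: pd.DataFrame, grid: MillerGrid, bounds) -> ReciprocalMap:
    """Symmetry-expand a merged table into a dense 3-D array.

    Every voxel within ``bounds`` whose ASU representative appears in the
    merged table receives that intensity; all others are NaN.
    """
    bounds = tuple((int(lo), int(hi)) for lo, hi in bounds)
    for lo, hi in bounds:
        if hi < lo:
            raise ValueError("bounds must satisfy hi >= lo")
    shape = tuple(hi - lo + 1 for lo, hi in bounds)
    axes = [np.arange(lo, hi + 1) for lo, hi in bounds]
    vox = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    asu, _, _ = map_to_asu(vox, grid)
    keys = pack_voxels(np.atleast_2d(asu))
    lookup = pd.Series(
        merged["I"].to_numpy(), index=merged["asu_key"].to_numpy()
    )
    values = lookup.reindex(keys).to_numpy(dtype=float)
    return ReciprocalMap(values.reshape(shape), bounds, grid)


def isotropic_curve(merged: pd.DataFrame, shells: ShellScheme, grid: MillerGrid):
    """Per-shell mean non-halo intensity and the shell centers."""
    halo = halo_partition(merged, grid)
    if not np.any(~halo):
        raise ValueError("no non-halo voxels to estimate the isotropic curve")
    s = merged["s"].to_numpy(dtype=float)[~halo]
    I = merged["I"].to_numpy(dtype=float)[~halo]
    idx = shells.assign(s)
    means = np.full(shells.n_shells, np.nan)
    for sh in range(shells.n_shells):
        sel = idx == sh
        if sel.any():
            means[sh] = I[sel].mean()
    ok = np.isfinite(means)
    if not ok.any():
        raise ValueError("no populated non-halo shells")
    return shells.centers[ok], means[ok]


def subtract_isotropic(
    merged: pd.DataFrame, shells: ShellScheme, grid: MillerGrid
) -> pd.DataFrame:
    """Subtract the isotropic (shell-mean, non-halo) component.

    The shell-mean curve is evaluated at each voxel's s by linear
    interpolation between shell centers (clamped at the ends).  Returns a
    copy of the merged table with columns ``I_iso`` and ``I_var`` where
    ``I = I_iso + I_var``.
    """
    centers, means = isotropic_curve(merged, shells, grid)
    s = merged["s"].to_numpy(dtype=float)
    iso = np.interp(s, centers, means)
    out = merged.copy()
    out["I_iso"] = iso
    out["I_var"] = out["I"] - iso
    return out
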