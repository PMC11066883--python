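"""Data splitting, shell correlation statistics and the halo partition.

Precision of merged diffuse intensities is quantified per resolution shell
(constant scattering-vector magnitude s) by Pearson correlation between two
merges: random half-data sets (CC₁/₂), halves split by Friedel symmetry —
whether the operator mapping an observation into the asymmetric unit is
improper (CC_Friedel) — or independently measured and scaled crystals
(CC_Rep).  Because halo voxels (integer Miller indices passing the
reflection condition) carry much stronger signal than the rest, statistics
are reported separately for the halo and non-halo partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_symmetry import MillerGrid, is_bragg_voxel
from .scaling import merge_scaled

__all__ = [
    "ShellScheme",
    "make_shells",
    "split_observations",
    "cc_by_shell",
    "cc_rep",
    "halo_partition",
    "shell_statistics",
]


@dataclass(frozen=True)
class ShellScheme:
    """Resolution shells: strictly increasing edges in s (Å⁻¹).

    Binning is half-open, [e_i, e_{i+1}); the last shell includes its upper
    edge so the full observed range is covered.
    """

    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("shell edges must be strictly increasing, >= 2 values")
        object.__setattr__(self, "edges", edges)

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, s) -> np.ndarray:
        """Shell index per s value; −1 for values outside the edges."""
        s = np.asarray(s, dtype=float)
        idx = np.searchsorted(self.edges, s, side="right") - 1
        idx = np.where(s == self.edges[-1], self.n_shells - 1, idx)
        idx = np.where((idx < 0) | (idx >= self.n_shells), -1, idx)
        return idx


def make_shells(s_values, n_shells: int = 20, mode: str = "equal_width") -> ShellScheme:
    """Shells in s spanning the observed range.

    ``equal_width`` slices the range evenly; ``equal_count`` places edges at
    quantiles so each shell holds about the same number of voxels (the
    better choice for correlation statistics, which are noisy in sparsely
    populated shells).
    """
    s = np.asarray(s_values, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite s values")
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        hi = lo + 1e-9
    if mode == "equal_width":
        return ShellScheme(np.linspace(lo, hi, n_shells + 1))
    if mode == "equal_count":
        edges = np.quantile(s, np.linspace(0, 1, n_shells + 1))
        edges[0], edges[-1] = lo, hi
        edges = np.unique(edges)
        if len(edges) < 2:
            edges = np.array([lo, hi])
        return ShellScheme(edges)
    raise ValueError(f"unknown shell mode {mode!r}")


def split_observations(obs: pd.DataFrame, mode: str, seed: int = 0):
    """Partition observations into two halves.

    ``randomHalf``: per ASU voxel, the voxel's observations are shuffled
    with a seeded generator and assigned alternately, starting with the half
    chosen by a per-voxel fair coin (so odd counts balance across voxels;
    per-voxel imbalance is at most 1).  ``Friedel``: split by whether the
    ASU-mapping operator is improper.  Returns ``(half1, half2)`` whose
    union is the input and whose intersection is empty.
    """
    if mode == "Friedel":
        label = obs["friedel"].to_numpy(dtype=bool)
    elif mode == "randomHalf":
        rng = np.random.default_rng(seed)
        codes, uniques = pd.factorize(obs["asu_key"], sort=True)
        r = rng.random(len(obs))
        coin = rng.integers(0, 2, size=len(uniques))
        order = np.lexsort((r, codes))
        sorted_codes = codes[order]
        # rank of each observation within its (shuffled) voxel group
        starts = np.r_[0, np.flatnonzero(np.diff(sorted_codes)) + 1]
        group_start = np.repeat(starts, np.diff(np.r_[starts, len(order)]))
        rank = np.arange(len(order)) - group_start
        label = np.empty(len(obs), dtype=bool)
        label[order] = (rank + coin[sorted_codes]) % 2 == 1
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return obs.loc[~label], obs.loc[label]


def _pearson_by_shell(joined: pd.DataFrame, shells: ShellScheme) -> pd.DataFrame:
    idx = shells.assign(joined["s"].to_numpy())
    cc = np.full(shells.n_shells, np.nan)
    n = np.zeros(shells.n_shells, dtype=int)
    for sh in range(shells.n_shells):
        sel = idx == sh
        n[sh] = int(sel.sum())
        if n[sh] >= 3:
            x = joined.loc[sel, "I_1"].to_numpy()
            y = joined.loc[sel, "I_2"].to_numpy()
            sx, sy = x.std(), y.std()
            if sx > 0 and sy > 0:
                cc[sh] = float(np.corrcoef(x, y)[0, 1])
    return pd.DataFrame(
        {
            "s_min": shells.edges[:-1],
            "s_max": shells.edges[1:],
            "n_common": n,
            "cc": cc,
        }
    )


def cc_by_shell(
    merged1: pd.DataFrame, merged2: pd.DataFrame, shells: ShellScheme
) -> pd.DataFrame:
    """Pearson correlation per shell over ASU voxels present in both merges.

    Shells with fewer than 3 common voxels get NaN (undefined marker).
    """
    joined = merged1.merge(
        merged2[["asu_key", "I"]], on="asu_key", suffixes=("_1", "_2"), how="inner"
    ).rename(columns={"I_x": "I_1", "I_y": "I_2"})
    if "I_1" not in joined.columns:  # pandas names depend on overlap
        joined = joined.rename(columns={"I": "I_1"})
    return _pearson_by_shell(joined, shells)


def cc_rep(
    obs: pd.DataFrame,
    group1,
    group2,
    shells: ShellScheme,
    refine_fn=None,
    config=None,
) -> pd.DataFrame:
    """Reproducibility correlation between independently scaled crystals.

    ``group1``/``group2`` are disjoint sets of batch (sweep) identifiers;
    each group is scaled and merged independently (with ``refine_fn``,
    default :func:`dsmap.scaling.refine`, or a plain unscaled merge when
    ``refine_fn`` is ``False``) and the two merges are correlated per shell.
    """
    g1, g2 = set(group1), set(group2)
    if g1 & g2:
        raise ValueError(f"batch groups overlap: {sorted(g1 & g2)}")
    merges = []
    for group in (g1, g2):
        sub = obs.loc[obs["batch"].isin(group)]
        if refine_fn is False:
            merges.append(merge_scaled(sub))
        else:
            fn = refine_fn
            if fn is None:
                from .scaling import refine as fn  # local import avoids cycle
            _, merged, _ = fn(sub, config) if config is not None else fn(sub)
            merges.append(merged)
    return cc_by_shell(merges[0], merges[1], shells)


def halo_partition(merged: pd.DataFrame, grid: MillerGrid) -> np.ndarray:
    """Boolean per merged voxel: True where the voxel center is an integer
    hkl node passing the centering reflection condition ('halo')."""
    vox = merged[["i", "j", "k"]].to_numpy(dtype=np.int64)
    return np.atleast_1d(is_bragg_voxel(vox, grid))


def shell_statistics(
    merged: pd.DataFrame, shells: ShellScheme, is_halo
) -> pd.DataFrame:
    """Mean and SD of merged intensity per shell per partition.

    All values are divided by a single normalization constant: the maximum
    over shells of the non-halo mean.  Empty (shell, partition) cells get
    NaN.  Returns one row per (shell, partition).
    """
    is_halo = np.asarray(is_halo, dtype=bool)
    s = merged["s"].to_numpy(dtype=float)
    I = merged["I"].to_numpy(dtype=float)
    idx = shells.assign(s)
    rows = []
    means = {}
    for part, sel_part in (("non-halo", ~is_halo), ("halo", is_halo)):
        for sh in range(shells.n_shells):
            sel = sel_part & (idx == sh)
            n = int(sel.sum())
            mean = float(I[sel].mean()) if n else np.nan
            sd = float(I[sel].std(ddof=1)) if n >= 2 else np.nan
            means.setdefault(part, []).append(mean)
            rows.append(
                {
                    "shell": sh,
                    "s_min": shells.edges[sh],
                    "s_max": shells.edges[sh + 1],
                    "partition": part,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                }
            )
    non_halo_means = np.asarray(means["non-halo"], dtype=float)
    if np.all(np.isnan(non_halo_means)):
        raise ValueError("no non-halo voxels in any shell")
    norm = np.nanmax(non_halo_means)
    out = pd.DataFrame(rows)
    out["mean"] = out["mean"] / norm
    out["sd"] = out["sd"] / norm
    return out
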