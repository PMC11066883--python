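"""Reciprocal-space voxel grids, reflection conditions and Laue symmetry.

Diffuse scattering is accumulated on a grid of voxels whose centers lie at
fractional Miller indices ``(i/n_h, j/n_k, k/n_l)`` for an integer
subdivision ``n`` of the reciprocal unit cell along each axis.  This module
provides the grid geometry (nearest-voxel assignment, scattering-vector
magnitudes), lattice-centering reflection conditions, and the mapping of
voxels onto an asymmetric unit under a Laue group (a centrosymmetric point
group acting on Miller indices by integer matrices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "MillerGrid",
    "laue_group_ops",
    "voxel_of",
    "voxel_center",
    "is_bragg_voxel",
    "centering_allowed",
    "count_diffuse_voxels",
    "map_to_asu",
    "orbit",
    "s_magnitude",
    "modulation_wavelength",
    "pack_voxels",
    "unpack_voxels",
]

_CENTERINGS = ("P", "I", "F", "C")


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")

    @classmethod
    def cubic(cls, a: float) -> "UnitCell":
        return cls(a, a, a, 90.0, 90.0, 90.0)

    @property
    def is_cubic(self) -> bool:
        return (
            math.isclose(self.a, self.b)
            and math.isclose(self.b, self.c)
            and all(
                math.isclose(getattr(self, n), 90.0)
                for n in ("alpha", "beta", "gamma")
            )
        )

    def direct_metric(self) -> np.ndarray:
        """Metric tensor G of the direct lattice (Å²)."""
        ca, cb, cg = (
            math.cos(math.radians(self.alpha)),
            math.cos(math.radians(self.beta)),
            math.cos(math.radians(self.gamma)),
        )
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Metric tensor G* of the reciprocal lattice (Å⁻²); s² = hᵀ G* h."""
        return np.linalg.inv(self.direct_metric())


def _closure(generators: Iterable[np.ndarray]) -> np.ndarray:
    """Close a set of integer 3x3 matrices under multiplication."""
    seen = {}
    frontier = [np.asarray(g, dtype=int) for g in generators]
    ident = np.eye(3, dtype=int)
    frontier.append(ident)
    for g in frontier:
        seen[g.tobytes()] = g
    while frontier:
        g = frontier.pop()
        for h in list(seen.values()):
            for p in (g @ h, h @ g):
                key = p.tobytes()
                if key not in seen:
                    seen[key] = p
                    frontier.append(p)
    # identity first, then a deterministic order
    ops = sorted(seen.values(), key=lambda m: tuple(m.ravel()))
    ops.sort(key=lambda m: 0 if np.array_equal(m, ident) else 1)
    return np.array(ops)


def laue_group_ops(name: str) -> np.ndarray:
    """Laue-group operator preset: (n_ops, 3, 3) integer matrices.

    ``"m-3"`` (equivalently the space-group label ``"I213"``) is the Laue
    group of point group 23: its 12 proper rotations closed under inversion,
    24 operators total.  ``"-1"`` gives just {1, −1}.
    """
    key = name.replace(" ", "").lower()
    if key in ("m-3", "m-3bar", "m3bar", "i213", "23", "p213"):
        two_z = np.diag([-1, -1, 1])
        two_x = np.diag([1, -1, -1])
        three_111 = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
        rotations = _closure([two_z, two_x, three_111])
        if len(rotations) != 12:  # pragma: no cover - sanity
            raise RuntimeError("point group 23 closure failed")
    elif key in ("-1", "ci"):
        rotations = np.eye(3, dtype=int)[None]
    else:
        raise ValueError(f"unknown Laue group preset: {name!r}")
    ops = np.concatenate([rotations, -rotations])
    return _sort_ops(ops)


def _sort_ops(ops: np.ndarray) -> np.ndarray:
    ident = np.eye(3, dtype=int)
    ops = sorted((np.asarray(o, dtype=int) for o in ops), key=lambda m: tuple(m.ravel()))
    ops.sort(key=lambda m: 0 if np.array_equal(m, ident) else 1)
    return np.array(ops)


@dataclass(frozen=True)
class MillerGrid:
    """Oversampled reciprocal-lattice voxel grid with Laue symmetry.

    Voxel centers lie at fractional hkl ``(i/n_h, j/n_k, k/n_l)``.  The
    operator list must form a centrosymmetric group (closed, containing the
    identity and −R for every R).
    """

    cell: UnitCell
    subdivision: tuple[int, int, int] = (3, 3, 3)
    centering: str = "P"
    laue_ops: np.ndarray = field(
        default_factory=lambda: laue_group_ops("-1"), compare=False
    )

    def __post_init__(self):
        sub = self.subdivision
        if isinstance(sub, (int, np.integer)):
            sub = (int(sub),) * 3
        sub = tuple(int(n) for n in sub)
        if len(sub) != 3 or any(n < 1 for n in sub):
            raise ValueError("subdivision must be three positive integers")
        object.__setattr__(self, "subdivision", sub)
        if self.centering not in _CENTERINGS:
            raise ValueError(f"unknown centering {self.centering!r}")
        ops = np.asarray(self.laue_ops, dtype=int)
        if ops.ndim != 3 or ops.shape[1:] != (3, 3) or len(ops) == 0:
            raise ValueError("laue_ops must be a non-empty (n, 3, 3) array")
        keys = {op.tobytes() for op in ops}
        if np.eye(3, dtype=int).tobytes() not in keys:
            raise ValueError("laue_ops must contain the identity")
        for op in ops:
            if (-op).tobytes() not in keys:
                raise ValueError("Laue groups are centrosymmetric: missing -R")
            for other in ops:
                if (op @ other).tobytes() not in keys:
                    raise ValueError("laue_ops not closed under composition")
        object.__setattr__(self, "laue_ops", _sort_ops(ops))
        dets = np.rint(np.linalg.det(self.laue_ops)).astype(int)
        object.__setattr__(self, "_op_dets", dets)

    @classmethod
    def from_preset(
        cls,
        cell: UnitCell,
        subdivision=3,
        centering: str = "I",
        laue: str = "m-3",
    ) -> "MillerGrid":
        return cls(cell, subdivision, centering, laue_group_ops(laue))

    @property
    def op_determinants(self) -> np.ndarray:
        return self._op_dets


def _as_points(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    return np.atleast_2d(arr), single


def voxel_of(hkl_frac, grid: MillerGrid) -> np.ndarray:
    """Nearest-voxel indices for fractional Miller indices.

    Ties (fraction exactly halfway between voxel centers) round half to even
    on each axis independently.
    """
    pts, single = _as_points(hkl_frac)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite fractional Miller indices")
    sub = np.asarray(grid.subdivision, dtype=float)
    v = np.rint(pts * sub).astype(np.int64)
    return v[0] if single else v


def voxel_center(v, grid: MillerGrid) -> np.ndarray:
    """Fractional Miller indices of the voxel center(s)."""
    arr = np.asarray(v, dtype=float)
    return arr / np.asarray(grid.subdivision, dtype=float)


def centering_allowed(hkl, centering: str) -> np.ndarray:
    """Reflection condition for integer Miller indices under a centering."""
    pts = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    h, k, l = pts[:, 0], pts[:, 1], pts[:, 2]
    if centering == "P":
        out = np.ones(len(pts), dtype=bool)
    elif centering == "I":
        out = (h + k + l) % 2 == 0
    elif centering == "F":
        out = (h % 2 == k % 2) & (k % 2 == l % 2)
    elif centering == "C":
        out = (h + k) % 2 == 0
    else:
        raise ValueError(f"unknown centering {centering!r}")
    return out[0] if np.asarray(hkl).ndim == 1 else out


def is_bragg_voxel(v, grid: MillerGrid) -> np.ndarray:
    """True iff the voxel center is an integer hkl node passing the
    centering reflection condition (e.g. h+k+l = 2n for I)."""
    arr = np.atleast_2d(np.asarray(v, dtype=np.int64))
    sub = np.asarray(grid.subdivision, dtype=np.int64)
    integer = np.all(arr % sub == 0, axis=1)
    hkl = arr // sub
    allowed = centering_allowed(hkl, grid.centering)
    out = integer & allowed
    return out[0] if np.asarray(v).ndim == 1 else out


def count_diffuse_voxels(subdivision: int, centering: str) -> int:
    """Diffuse (non-Bragg) voxels per Bragg peak, by exhaustive enumeration
    over two reciprocal cells per axis (one full centering period)."""
    n = int(subdivision)
    if n < 1:
        raise ValueError("subdivision must be >= 1")
    if centering not in _CENTERINGS:
        raise ValueError(f"unknown centering {centering!r}")
    grid = MillerGrid(UnitCell.cubic(1.0), (n, n, n), centering)
    rng = np.arange(2 * n)
    vox = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    bragg = is_bragg_voxel(vox, grid)
    n_bragg = int(bragg.sum())
    total = len(vox)
    return total // n_bragg - 1


def _lex_greater(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise lexicographic a > b for (N, 3) integer arrays."""
    gt0 = a[:, 0] > b[:, 0]
    eq0 = a[:, 0] == b[:, 0]
    gt1 = a[:, 1] > b[:, 1]
    eq1 = a[:, 1] == b[:, 1]
    gt2 = a[:, 2] > b[:, 2]
    return gt0 | (eq0 & (gt1 | (eq1 & gt2)))


def map_to_asu(v, grid: MillerGrid):
    """Map voxel(s) to the asymmetric-unit representative.

    The representative is the lexicographically greatest image of ``v``
    under all Laue operators (deterministic and constant on orbits).
    Returns ``(asu_voxel, op_index, friedel)`` where ``friedel`` is True iff
    the selected operator is improper (det = −1).  Ties between operators
    yielding the same image are broken by the lowest operator index, with
    the identity ordered first.
    """
    arr = np.atleast_2d(np.asarray(v, dtype=np.int64))
    ops = grid.laue_ops
    images = np.einsum("oij,nj->oni", ops, arr)
    best = images[0].copy()
    best_op = np.zeros(len(arr), dtype=np.int64)
    for idx in range(1, len(ops)):
        better = _lex_greater(images[idx], best)
        best[better] = images[idx][better]
        best_op[better] = idx
    friedel = grid.op_determinants[best_op] < 0
    if np.asarray(v).ndim == 1:
        return best[0], int(best_op[0]), bool(friedel[0])
    return best, best_op, friedel


def orbit(v, grid: MillerGrid) -> np.ndarray:
    """Distinct images of a single voxel under the Laue group."""
    arr = np.asarray(v, dtype=np.int64)
    images = np.einsum("oij,j->oi", grid.laue_ops, arr)
    return np.unique(images, axis=0)


def s_magnitude(hkl_frac, cell: UnitCell) -> np.ndarray:
    """Scattering-vector magnitude |s| in Å⁻¹ via the reciprocal metric.

    For a cubic cell this reduces to sqrt(h²+k²+l²)/a; resolution = 1/s.
    """
    pts, single = _as_points(hkl_frac)
    gstar = cell.reciprocal_metric()
    s2 = np.einsum("ni,ij,nj->n", pts, gstar, pts)
    s = np.sqrt(np.maximum(s2, 0.0))
    return float(s[0]) if single else s


def modulation_wavelength(q_frac: float, cell: UnitCell) -> float:
    """Real-space wavelength (Å) of a lattice modulation at fractional
    reciprocal offset ``q_frac`` from a Bragg node (cubic cells only)."""
    if not cell.is_cubic:
        raise ValueError("modulation_wavelength requires a cubic cell")
    if not q_frac > 0:
        raise ValueError("q_frac must be positive")
    return cell.a / float(q_frac)


_PACK_OFFSET = 1 << 20
_PACK_BITS = 21


def pack_voxels(v) -> np.ndarray:
    """Pack (i, j, k) voxel indices into a single int64 key."""
    arr = np.atleast_2d(np.asarray(v, dtype=np.int64))
    if np.any(np.abs(arr) >= _PACK_OFFSET):
        raise ValueError("voxel index out of packable range")
    shifted = arr + _PACK_OFFSET
    key = (shifted[:, 0] << (2 * _PACK_BITS)) | (shifted[:, 1] << _PACK_BITS) | shifted[:, 2]
    return key[0] if np.asarray(v).ndim == 1 else key


def unpack_voxels(key) -> np.ndarray:
    """Inverse of :func:`pack_voxels`."""
    k = np.atleast_1d(np.asarray(key, dtype=np.int64))
    mask = (1 << _PACK_BITS) - 1
    i = (k >> (2 * _PACK_BITS)) & mask
    j = (k >> _PACK_BITS) & mask
    kk = k & mask
    out = np.stack([i, j, kk], axis=-1) - _PACK_OFFSET
    return out[0] if np.ndim(key) == 0 else out
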