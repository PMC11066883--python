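"""Scaling model, regularized least squares, and inverse-variance merging.

Equivalent diffuse observations disagree because of systematic errors:
changes in illuminated volume as the crystal rotates, absorption of the
diffracted beam, detector flat-field errors and residual background.  The
scaling model predicts each observation from the merged ("true") intensity
I₀ via a linear transformation

    I_pred(i) = m_i · I₀(h_i) + o_i,      m = a·b·d,   o = a·c·d

with four physically motivated terms, each linearly interpolated from a
grid of control points over its scan coordinates:

    a(x, y, φ)  absorption            (scale)
    b(φ)        illuminated volume    (scale)
    c(s, φ)     background offset     (offset, restrained ≥ 0)
    d(x, y)     detector flat field   (scale, global over sweeps)

Refinement alternates between (i) inverse-variance merging of the
inverse-scaled observations and (ii) a regularized linear least-squares fit
of one parameter at a time with the others fixed, minimizing

    ‖A x − b‖² + Σ_k λ_k ‖B_k x‖²

where the regularizers B_k are discrete second-derivative operators (φ and
s axes), 2-D Laplacians (detector axes) and, for the offset, an identity
penalty that keeps the correction as small as the data allow.  Each
user-facing regularization weight α is re-normalized to
λ = α·‖A‖²_F/‖B‖²_F so that a given α behaves comparably across grid sizes
and noise levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import MatrixRankWarning, spsolve

from .grid_symmetry import unpack_voxels

__all__ = [
    "interp_operator",
    "second_derivative_operator",
    "laplacian_operator",
    "ParamGrid",
    "ScalingModel",
    "LeastSquaresProblem",
    "merge_scaled",
    "assemble_problem",
    "renormalize_alpha",
    "fit_parameter",
    "restrain_offset",
    "RefinementConfig",
    "refine",
]

PARAM_COORDS = {
    "a": ("x", "y", "phi"),
    "b": ("phi",),
    "c": ("s", "phi"),
    "d": ("x", "y"),
}

REFINEMENT_ORDER = ("b", "c", "a", "d")


# ---------------------------------------------------------------------------
# operators


def interp_operator(points, axes) -> sparse.csr_matrix:
    """Sparse multilinear-interpolation operator.

    Row i holds the weights of query point i over its 2^dim surrounding
    control points (queries clamped into the axis range).  Rows sum to 1
    and all entries are non-negative.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    axes = [np.asarray(ax, dtype=float) for ax in axes]
    if pts.shape[1] != len(axes):
        raise ValueError("points dimensionality does not match axes")
    if not 1 <= len(axes) <= 3:
        raise ValueError("only 1-3 dimensional grids are supported")
    for ax in axes:
        if ax.size == 0:
            raise ValueError("empty grid axis")
        if ax.size > 1 and np.any(np.diff(ax) <= 0):
            raise ValueError("grid axes must be strictly increasing")
    n = len(pts)
    ndim = len(axes)
    shape = tuple(ax.size for ax in axes)
    lo, t = [], []
    for d, ax in enumerate(axes):
        if ax.size == 1:
            lo.append(np.zeros(n, dtype=np.int64))
            t.append(np.zeros(n))
        else:
            x = np.clip(pts[:, d], ax[0], ax[-1])
            i0 = np.clip(np.searchsorted(ax, x, side="right") - 1, 0, ax.size - 2)
            lo.append(i0)
            t.append((x - ax[i0]) / (ax[i0 + 1] - ax[i0]))
    cols, vals = [], []
    for bits in range(2**ndim):
        w = np.ones(n)
        idx = []
        for d in range(ndim):
            bit = (bits >> d) & 1
            w = w * (t[d] if bit else 1.0 - t[d])
            idx.append(np.minimum(lo[d] + bit, shape[d] - 1))
        cols.append(np.ravel_multi_index(idx, shape))
        vals.append(w)
    rows = np.tile(np.arange(n), 2**ndim)
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (rows, np.concatenate(cols))),
        shape=(n, int(np.prod(shape))),
    )
    mat.sum_duplicates()
    return mat


def second_derivative_operator(n: int) -> sparse.csr_matrix:
    """(n−2)×n discrete second derivative: rows of (1, −2, 1).

    Annihilates affine sequences; empty (zero-penalty) for n < 3.
    """
    if n < 3:
        return sparse.csr_matrix((0, max(n, 0)))
    rows = np.repeat(np.arange(n - 2), 3)
    cols = (np.arange(n - 2)[:, None] + np.arange(3)[None, :]).ravel()
    vals = np.tile([1.0, -2.0, 1.0], n - 2)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n - 2, n))


def laplacian_operator(nx: int, ny: int) -> sparse.csr_matrix:
    """5-point discrete Laplacian on the interior of an nx×ny grid.

    Acts on grids vectorized in C order (index = ix·ny + iy); annihilates
    planes α·x + β·y + γ.  Empty when there are no interior points.
    """
    if nx < 3 or ny < 3:
        return sparse.csr_matrix((0, max(nx, 0) * max(ny, 0)))
    ix, iy = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    nrows = len(ix)
    rows = np.repeat(np.arange(nrows), 5)
    center = ix * ny + iy
    cols = np.stack(
        [center, center - ny, center + ny, center - 1, center + 1], axis=1
    ).ravel()
    vals = np.tile([-4.0, 1.0, 1.0, 1.0, 1.0], nrows)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nrows, nx * ny))


# ---------------------------------------------------------------------------
# parameter grids and model


@dataclass
class ParamGrid:
    """One scaling-model parameter: control-point values on a 1-3D grid."""

    kind: str  # 'a', 'b', 'c' or 'd'
    axes: tuple
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in PARAM_COORDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        self.axes = tuple(np.asarray(ax, dtype=float) for ax in self.axes)
        if len(self.axes) != len(PARAM_COORDS[self.kind]):
            raise ValueError(f"parameter {self.kind} needs {PARAM_COORDS[self.kind]} axes")
        shape = tuple(ax.size for ax in self.axes)
        self.values = np.asarray(self.values, dtype=float).reshape(shape)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("control-point values must be finite")

    @classmethod
    def constant(cls, kind: str, axes, value: float | None = None) -> "ParamGrid":
        if value is None:
            value = 0.0 if kind == "c" else 1.0
        shape = tuple(np.asarray(ax).size for ax in axes)
        return cls(kind, tuple(axes), np.full(shape, float(value)))

    @property
    def n_params(self) -> int:
        return self.values.size

    def operator(self, coords) -> sparse.csr_matrix:
        return interp_operator(coords, self.axes)

    def evaluate(self, coords) -> np.ndarray:
        return self.operator(coords) @ self.values.ravel()

    def regularizers(self) -> list[tuple[str, sparse.csr_matrix]]:
        """Smoothness (and, for c, magnitude) operators on the vectorized grid."""
        shape = tuple(ax.size for ax in self.axes)
        eye = sparse.identity
        if self.kind == "b":
            return [("smooth", second_derivative_operator(shape[0]))]
        if self.kind == "d":
            return [("smooth", laplacian_operator(shape[0], shape[1]))]
        if self.kind == "c":
            ns, nphi = shape
            return [
                ("smooth", sparse.kron(second_derivative_operator(ns), eye(nphi), format="csr")),
                ("smooth", sparse.kron(eye(ns), second_derivative_operator(nphi), format="csr")),
                ("magnitude", eye(ns * nphi, format="csr")),
            ]
        # a: Laplacian over (x, y) per phi plane, second derivative along phi
        nx, ny, nphi = shape
        return [
            ("smooth", sparse.kron(laplacian_operator(nx, ny), eye(nphi), format="csr")),
            ("smooth", sparse.kron(eye(nx * ny), second_derivative_operator(nphi), format="csr")),
        ]


class ScalingModel:
    """Per-sweep a, b, c parameter grids plus one global detector grid d.

    ``params`` maps 'a'/'b'/'c' to ``{sweep: ParamGrid}`` and 'd' to a
    single ParamGrid.  Parameters absent from ``params`` are disabled and
    evaluate to the identity (1 for scales, 0 for the offset).
    """

    def __init__(self, params: dict):
        for kind in params:
            if kind not in PARAM_COORDS:
                raise ValueError(f"unknown parameter kind {kind!r}")
        self.params = params

    @property
    def enabled(self) -> tuple[str, ...]:
        return tuple(k for k in ("a", "b", "c", "d") if k in self.params)

    def param_values(self, kind: str, obs: pd.DataFrame) -> np.ndarray:
        default = 0.0 if kind == "c" else 1.0
        if kind not in self.params:
            return np.full(len(obs), default)
        cols = list(PARAM_COORDS[kind])
        if kind == "d":
            return self.params["d"].evaluate(obs[cols].to_numpy(dtype=float))
        out = np.full(len(obs), np.nan)
        batch = obs["batch"].to_numpy()
        for sweep, g in self.params[kind].items():
            idx = batch == sweep
            if idx.any():
                out[idx] = g.evaluate(obs.loc[idx, cols].to_numpy(dtype=float))
        if np.any(np.isnan(out)):
            missing = sorted(set(batch) - set(self.params[kind]))
            raise KeyError(f"no {kind!r} grid for sweeps {missing}")
        return out

    def scales_for(self, obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-observation scale m = a·b·d and offset o = a·c·d."""
        a = self.param_values("a", obs)
        b = self.param_values("b", obs)
        c = self.param_values("c", obs)
        d = self.param_values("d", obs)
        return a * b * d, a * c * d


# ---------------------------------------------------------------------------
# merging


def _merge_arrays(I, sigma, m, o, codes, ncodes, use):
    """Inverse-variance merge per ASU-voxel code; returns (I0, sigma0, n)."""
    sigma_scaled = np.where(use, sigma / m, np.inf)
    i_scaled = np.where(use, (I - o) / m, 0.0)
    w = np.zeros(len(I))
    w[use] = 1.0 / sigma_scaled[use] ** 2
    sum_w = np.bincount(codes, weights=w, minlength=ncodes)
    sum_wi = np.bincount(codes, weights=w * i_scaled, minlength=ncodes)
    n_obs = np.bincount(codes[use], minlength=ncodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        i0 = np.where(sum_w > 0, sum_wi / np.where(sum_w > 0, sum_w, 1.0), np.nan)
        sigma0 = np.where(sum_w > 0, 1.0 / np.sqrt(np.where(sum_w > 0, sum_w, 1.0)), np.nan)
    return i0, sigma0, n_obs


def merge_scaled(obs: pd.DataFrame, model: ScalingModel | None = None) -> pd.DataFrame:
    """Merge equivalent observations with inverse-variance weights.

    Observations are inverse-scaled, I_scaled = (I − o)/m with
    σ_scaled = σ/m, then averaged per ASU voxel with weights σ_scaled⁻².
    Observations with σ ≤ 0 (zero counts) are excluded; voxels with no
    usable observation are absent from the output.
    """
    I = obs["I"].to_numpy(dtype=float)
    sigma = obs["sigma"].to_numpy(dtype=float)
    if model is not None:
        m, o = model.scales_for(obs)
    else:
        m, o = np.ones(len(obs)), np.zeros(len(obs))
    codes, uniques = pd.factorize(obs["asu_key"], sort=True)
    use = (sigma > 0) & np.isfinite(I)
    i0, sigma0, n_obs = _merge_arrays(I, sigma, m, o, codes, len(uniques), use)
    s_vals = np.full(len(uniques), np.nan)
    used_codes = codes[use]
    s_vals[used_codes[::-1]] = obs["s"].to_numpy(dtype=float)[use][::-1]
    present = n_obs > 0
    vox = np.atleast_2d(unpack_voxels(np.asarray(uniques, dtype=np.int64)[present]))
    return pd.DataFrame(
        {
            "asu_key": np.asarray(uniques, dtype=np.int64)[present],
            "i": vox[:, 0] if len(vox) else np.array([], dtype=np.int64),
            "j": vox[:, 1] if len(vox) else np.array([], dtype=np.int64),
            "k": vox[:, 2] if len(vox) else np.array([], dtype=np.int64),
            "s": s_vals[present],
            "I": i0[present],
            "sigma": sigma0[present],
            "n_obs": n_obs[present],
        }
    )


# ---------------------------------------------------------------------------
# least-squares problems


@dataclass
class LeastSquaresProblem:
    """Design matrix, target vector and weighted regularizers."""

    A: sparse.csr_matrix
    b: np.ndarray
    regularizers: list = field(default_factory=list)  # (name, B, alpha)

    def __post_init__(self):
        if self.A.shape[0] != len(self.b):
            raise ValueError("A rows must match target vector length")


def assemble_problem(
    kind: str,
    I,
    sigma,
    i0_obs,
    partner_values: dict,
    M: sparse.csr_matrix,
    regularizers,
    alphas: dict,
) -> LeastSquaresProblem:
    """Build the least-squares problem for one scaling parameter.

    ``partner_values`` holds the current per-observation values of all four
    parameters; the parameter being fit enters only through the design
    operator ``M`` (its interpolation matrix over the observations).
    """
    a = partner_values["a"]
    b_ = partner_values["b"]
    c = partner_values["c"]
    d = partner_values["d"]
    if kind == "a":
        w = d * (b_ * i0_obs + c) / sigma
        rhs = I / sigma
    elif kind == "b":
        w = d * a * i0_obs / sigma
        rhs = (I - a * c * d) / sigma
    elif kind == "c":
        w = d * a / sigma
        rhs = (I - a * b_ * d * i0_obs) / sigma
    elif kind == "d":
        w = a * (b_ * i0_obs + c) / sigma
        rhs = I / sigma
    else:
        raise ValueError(f"unknown parameter kind {kind!r}")
    A = sparse.diags(w) @ M
    regs = [
        (name, B, alphas["magnitude" if name == "magnitude" else "smooth"])
        for name, B in regularizers
    ]
    return LeastSquaresProblem(A.tocsr(), np.asarray(rhs, dtype=float), regs)


def renormalize_alpha(alpha: float, A: sparse.spmatrix, B: sparse.spmatrix) -> float:
    """λ = α · ‖A‖²_F / ‖B‖²_F (zero when B is empty or zero)."""
    b_fro2 = float(B.multiply(B).sum()) if B.shape[0] else 0.0
    if b_fro2 == 0.0:
        return 0.0
    a_fro2 = float(A.multiply(A).sum())
    return float(alpha) * a_fro2 / b_fro2


def fit_parameter(problem: LeastSquaresProblem) -> np.ndarray:
    """Solve the regularized normal equations for one parameter update."""
    A, b = problem.A, problem.b
    normal = (A.T @ A).tocsc()
    rhs = A.T @ b
    for _, B, alpha in problem.regularizers:
        lam = renormalize_alpha(alpha, A, B)
        if lam > 0:
            normal = normal + lam * (B.T @ B).tocsc()
    with warnings.catch_warnings():
        warnings.simplefilter("error", MatrixRankWarning)
        try:
            x = spsolve(normal, rhs)
        except (MatrixRankWarning, RuntimeError) as exc:
            raise ValueError(
                "singular normal matrix: the parameter is underdetermined; "
                "increase the regularization alpha or coarsen the grid"
            ) from exc
    if not np.all(np.isfinite(x)):
        raise ValueError(
            "singular normal matrix: the parameter is underdetermined; "
            "increase the regularization alpha or coarsen the grid"
        )
    return np.asarray(x, dtype=float)


def restrain_offset(values) -> np.ndarray:
    """Positivity restraint for the offset: clip negatives to zero; if all
    values are positive, subtract a constant so the minimum is zero."""
    arr = np.array(values, dtype=float, copy=True)
    if arr.size == 0:
        return arr
    if np.any(arr < 0):
        np.clip(arr, 0.0, None, out=arr)
    elif arr.min() > 0:
        arr -= arr.min()
    return arr


# ---------------------------------------------------------------------------
# refinement driver


@dataclass
class RefinementConfig:
    """Grid sizes, regularization weights and stopping conditions.

    Defaults: the primitive model refines only b(φ) (one control point per
    2.5° of rotation).  ``full_model()`` enables all four terms with the
    offset on a 15-point s grid × 5° φ grid, absorption on 5×5 detector
    points × 10° φ, and the flat field on a 200×200 detector grid.
    """

    enable_a: bool = False
    enable_b: bool = True
    enable_c: bool = False
    enable_d: bool = False
    b_phi_step: float = 2.5
    c_n_s: int = 15
    c_phi_step: float = 5.0
    a_nx: int = 5
    a_ny: int = 5
    a_phi_step: float = 10.0
    d_nx: int = 200
    d_ny: int = 200
    alpha_smooth: float = 1.0
    alpha_magnitude: float = 0.01
    max_cycles: int = 20
    tol: float = 1e-4
    outlier_sigma: float = 5.0
    x_range: tuple | None = None
    y_range: tuple | None = None

    @classmethod
    def full_model(cls, **kwargs) -> "RefinementConfig":
        return cls(enable_a=True, enable_b=True, enable_c=True, enable_d=True, **kwargs)

    @property
    def enabled(self) -> tuple[str, ...]:
        return tuple(
            k for k in REFINEMENT_ORDER if getattr(self, f"enable_{k}")
        )

    @property
    def alphas(self) -> dict:
        return {"smooth": self.alpha_smooth, "magnitude": self.alpha_magnitude}


def _axis_step(lo: float, hi: float, step: float) -> np.ndarray:
    if hi - lo <= 0:
        return np.array([lo])
    npts = max(2, int(np.ceil((hi - lo) / step)) + 1)
    return np.linspace(lo, hi, npts)


def _axis_n(lo: float, hi: float, n: int) -> np.ndarray:
    if hi - lo <= 0:
        return np.array([lo])
    return np.linspace(lo, hi, max(int(n), 2))


class _Refiner:
    def __init__(self, obs: pd.DataFrame, config: RefinementConfig):
        required = {"batch", "phi", "x", "y", "s", "I", "sigma", "asu_key"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observation table lacks columns {sorted(missing)}")
        self.obs = obs.reset_index(drop=True)
        self.config = config
        self.I = self.obs["I"].to_numpy(dtype=float)
        self.sigma = self.obs["sigma"].to_numpy(dtype=float)
        self.codes, self.uniques = pd.factorize(self.obs["asu_key"], sort=True)
        self.ncodes = len(self.uniques)
        self.usable = (self.sigma > 0) & np.isfinite(self.I)
        mult = np.bincount(self.codes[self.usable], minlength=self.ncodes)
        if not np.any(mult >= 2):
            raise ValueError(
                "scaling is vacuous: no ASU voxel has two or more usable observations"
            )
        self.outlier = np.zeros(len(self.obs), dtype=bool)
        self.batch = self.obs["batch"].to_numpy()
        self.sweeps = sorted(pd.unique(self.obs["batch"]))
        self.sweep_rows = {sw: np.flatnonzero(self.batch == sw) for sw in self.sweeps}
        self.model = self._init_model()
        self._ops: dict = {}
        self._values_cache: dict = {}

    # -- model construction -------------------------------------------------
    def _init_model(self) -> ScalingModel:
        cfg = self.config
        obs = self.obs
        params: dict = {}
        x_lo, x_hi = (
            cfg.x_range
            if cfg.x_range is not None
            else (obs["x"].min(), obs["x"].max())
        )
        y_lo, y_hi = (
            cfg.y_range
            if cfg.y_range is not None
            else (obs["y"].min(), obs["y"].max())
        )
        s_lo, s_hi = obs["s"].min(), obs["s"].max()
        for kind in cfg.enabled:
            if kind == "d":
                axes = (_axis_n(x_lo, x_hi, cfg.d_nx), _axis_n(y_lo, y_hi, cfg.d_ny))
                params["d"] = ParamGrid.constant("d", axes)
                continue
            per_sweep = {}
            for sw in self.sweeps:
                rows = self.sweep_rows[sw]
                p_lo = obs["phi"].to_numpy()[rows].min()
                p_hi = obs["phi"].to_numpy()[rows].max()
                if kind == "b":
                    axes = (_axis_step(p_lo, p_hi, cfg.b_phi_step),)
                elif kind == "c":
                    axes = (
                        _axis_n(s_lo, s_hi, cfg.c_n_s),
                        _axis_step(p_lo, p_hi, cfg.c_phi_step),
                    )
                else:  # a
                    axes = (
                        _axis_n(x_lo, x_hi, cfg.a_nx),
                        _axis_n(y_lo, y_hi, cfg.a_ny),
                        _axis_step(p_lo, p_hi, cfg.a_phi_step),
                    )
                per_sweep[sw] = ParamGrid.constant(kind, axes)
            params[kind] = per_sweep
        return ScalingModel(params)

    # -- cached per-sweep interpolation operators ---------------------------
    def _op(self, kind: str, sweep) -> sparse.csr_matrix:
        key = (kind, sweep)
        if key not in self._ops:
            cols = list(PARAM_COORDS[kind])
            if kind == "d":
                coords = self.obs[cols].to_numpy(dtype=float)
                grid = self.model.params["d"]
            else:
                rows = self.sweep_rows[sweep]
                coords = self.obs.iloc[rows][cols].to_numpy(dtype=float)
                grid = self.model.params[kind][sweep]
            self._ops[key] = grid.operator(coords)
        return self._ops[key]

    def _param_values(self, kind: str) -> np.ndarray:
        """Per-observation values of one parameter (cached ops)."""
        default = 0.0 if kind == "c" else 1.0
        if kind not in self.model.params:
            return np.full(len(self.obs), default)
        if kind == "d":
            return self._op("d", None) @ self.model.params["d"].values.ravel()
        out = np.empty(len(self.obs))
        for sw in self.sweeps:
            rows = self.sweep_rows[sw]
            out[rows] = self._op(kind, sw) @ self.model.params[kind][sw].values.ravel()
        return out

    def _scales(self):
        vals = {k: self._param_values(k) for k in ("a", "b", "c", "d")}
        return vals, vals["a"] * vals["b"] * vals["d"], vals["a"] * vals["c"] * vals["d"]

    # -- refinement steps ---------------------------------------------------
    def _merge(self, m, o):
        use = self.usable & ~self.outlier
        return _merge_arrays(self.I, self.sigma, m, o, self.codes, self.ncodes, use)

    def _fit_kind(self, kind: str):
        cfg = self.config
        vals, m, o = self._scales()
        i0_vox, _, _ = self._merge(m, o)
        i0_obs = i0_vox[self.codes]
        use = self.usable & ~self.outlier & np.isfinite(i0_obs)
        if kind == "d":
            rows = np.flatnonzero(use)
            grid = self.model.params["d"]
            M = self._op("d", None)[rows]
            problem = assemble_problem(
                kind,
                self.I[rows],
                self.sigma[rows],
                i0_obs[rows],
                {k: vals[k][rows] for k in vals},
                M,
                grid.regularizers(),
                cfg.alphas,
            )
            grid.values = fit_parameter(problem).reshape(grid.values.shape)
            return
        for sw in self.sweeps:
            rows = self.sweep_rows[sw]
            sel = use[rows]
            if not sel.any():
                continue
            grid = self.model.params[kind][sw]
            M = self._op(kind, sw)[sel]
            ridx = rows[sel]
            problem = assemble_problem(
                kind,
                self.I[ridx],
                self.sigma[ridx],
                i0_obs[ridx],
                {k: vals[k][ridx] for k in vals},
                M,
                grid.regularizers(),
                cfg.alphas,
            )
            x = fit_parameter(problem)
            if kind == "c":
                x = restrain_offset(x)
            grid.values = x.reshape(grid.values.shape)

    def _gauge_fix(self):
        if "b" not in self.model.params:
            return
        all_b = np.concatenate(
            [g.values.ravel() for g in self.model.params["b"].values()]
        )
        g = all_b.mean()
        if g != 0:
            for grid in self.model.params["b"].values():
                grid.values = grid.values / g

    def _chi2(self):
        _, m, o = self._scales()
        i0_vox, _, _ = self._merge(m, o)
        i0_obs = i0_vox[self.codes]
        use = self.usable & ~self.outlier & np.isfinite(i0_obs)
        r = (self.I[use] - m[use] * i0_obs[use] - o[use]) / self.sigma[use]
        return float(np.sum(r * r)), int(use.sum()), m, o, i0_obs

    def run(self):
        cfg = self.config
        history = []
        n_rising = 0
        converged = False
        for cycle in range(cfg.max_cycles):
            for kind in cfg.enabled:
                self._fit_kind(kind)
            self._gauge_fix()
            chi2, n_use, m, o, i0_obs = self._chi2()
            history.append(chi2 / max(n_use, 1))
            # outlier rejection between cycles
            resid = np.abs(self.I - m * i0_obs - o) / np.where(
                self.sigma > 0, self.sigma, np.inf
            )
            new_out = self.usable & np.isfinite(i0_obs) & (resid > cfg.outlier_sigma)
            self.outlier |= new_out
            if len(history) >= 2:
                prev, cur = history[-2], history[-1]
                if cur > prev:
                    n_rising += 1
                    if n_rising >= 3:
                        raise RuntimeError(
                            "scaling refinement diverged: chi2 rose for three "
                            f"consecutive cycles; history={history}"
                        )
                else:
                    n_rising = 0
                if abs(cur - prev) <= cfg.tol * max(abs(prev), 1e-300):
                    converged = True
                    break
        _, m, o = self._scales()
        use = self.usable & ~self.outlier
        i0, sigma0, n_obs = _merge_arrays(
            self.I, self.sigma, m, o, self.codes, self.ncodes, use
        )
        merged_obs = self.obs.loc[use].copy()
        merged = merge_scaled(
            merged_obs.assign(
                I=(self.I[use] - o[use]) / m[use], sigma=self.sigma[use] / m[use]
            )
        )
        diagnostics = {
            "chi2_per_obs": history,
            "cycles": len(history),
            "converged": converged,
            "n_outliers": int(self.outlier.sum()),
            "m": m,
            "o": o,
            "outlier": self.outlier.copy(),
        }
        return self.model, merged, diagnostics


def refine(obs: pd.DataFrame, config: RefinementConfig | None = None):
    """Refine the scaling model by regularized alternating least squares.

    Each cycle merges the inverse-scaled observations and then refits each
    enabled parameter in the order b → c → a → d (offset restrained after
    each fit), applies gauge fixing (mean of b over all sweeps = 1), rejects
    outliers (scaled residuals beyond ``outlier_sigma``), and halts when the
    relative change of χ² per observation falls below ``tol`` or after
    ``max_cycles``.  Returns ``(model, merged_table, diagnostics)``.
    """
    return _Refiner(obs, config or RefinementConfig()).run()
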