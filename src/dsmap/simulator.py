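"""Synthetic rotation-series diffuse scattering with known ground truth.

The simulator emulates the essential statistics of a fine φ-sliced rotation
experiment on an I-centered cubic crystal (Laue group m-3̄, cell edge
79.48 Å by default): Poisson photon counting; a smooth isotropic diffuse
profile peaking near 3 Å resolution (s ≈ 0.33 Å⁻¹); a band-limited
variational component symmetrized over the Laue group; halo scattering
decaying as the inverse square of the distance from allowed
reciprocal-lattice nodes; multiplicative artifact fields matching the
scaling model (illuminated volume b(φ), absorption a(x,y,φ), detector flat
field d(x,y) with a low-response chip and panel-edge attenuation) and an
additive background/offset field c(s,φ); and a constant instrument
background rate.

Two output modes are provided.  Observation mode emits per-voxel
observation tables with fractional Miller indices already assigned (the
default; diffraction geometry is not ray-traced).  Image mode rasterizes a
small synthetic detector with per-pixel fractional hkl and optional Bragg
spikes, for exercising peak masking, background binning and integration.
All randomness derives from a single seed; per-sweep substreams are spawned
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corrections import CorrectionFactors, correct_observation
from .grid_symmetry import (
    MillerGrid,
    UnitCell,
    centering_allowed,
    map_to_asu,
    pack_voxels,
    s_magnitude,
    voxel_center,
    voxel_of,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_truth", "simulate_sweep",
           "simulate_experiment", "simulate_images", "apply_corrections"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate a fine-sliced rotation series: cubic cell a = 79.48 Å,
    I centering, threefold oversampling, two 50° sweeps at 0.1°/frame and
    0.1 s exposure per frame.  Intensities are in photons·s⁻¹ per voxel
    solid angle; the isotropic profile peaks at s ≈ 0.33 Å⁻¹ (≈3 Å).
    """

    cell_a: float = 79.48
    subdivision: int = 3
    centering: str = "I"
    n_sweeps: int = 2
    phi_range: float = 50.0
    dphi: float = 0.1
    exposure_per_frame: float = 0.1
    obs_per_sweep: int = 50_000
    n_voxels: int = 4_000
    pixels_per_obs: int = 50
    detector_shape: tuple = (512, 512)
    s_min: float = 0.05
    s_max: float = 0.7
    # truth: isotropic + variational + halo
    iso_scale: float = 20.0
    iso_peak_s: float = 0.33
    iso_width: float = 0.12
    iso_floor: float = 0.15
    var_amplitude: float = 1.0
    var_n_waves: int = 8
    halo_amplitude: float = 0.5
    halo_epsilon: float = 0.005
    halo_mask_radius: float = 0.102
    # artifact amplitudes (0 disables)
    amp_b: float = 0.3
    amp_a: float = 0.1
    amp_c: float = 3.0
    chip_drop: float = 0.15
    edge_drop: float = 0.2
    background_rate: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.exposure_per_frame <= 0 or self.dphi <= 0:
            raise ValueError("exposures and rotation steps must be positive")
        for name in ("iso_scale", "var_amplitude", "halo_amplitude", "amp_b",
                     "amp_a", "amp_c", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def make_grid(self) -> MillerGrid:
        return MillerGrid.from_preset(
            UnitCell.cubic(self.cell_a), self.subdivision, self.centering, "m-3"
        )

    @classmethod
    def from_text(cls, text: str) -> "SimulationConfig":
        """Parse a plain-text ``key = value`` configuration."""
        kwargs = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown simulation parameter {key!r}")
            current = getattr(cls, key, cls.__dataclass_fields__[key].default)
            if key == "detector_shape":
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key == "centering":
                kwargs[key] = value
            elif isinstance(current, int) and not isinstance(current, bool):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Deterministic truth fields for one simulated experiment."""

    config: SimulationConfig
    grid: MillerGrid
    var_dirs: np.ndarray    # (n_waves, 3) wavevectors of the variational field
    var_phases: np.ndarray
    var_coefs: np.ndarray
    b_phases: np.ndarray    # per sweep
    a_phases: np.ndarray
    c_scales: np.ndarray

    # -- diffuse intensity --------------------------------------------------
    def isotropic(self, s) -> np.ndarray:
        cfg = self.config
        s = np.asarray(s, dtype=float)
        bump = np.exp(-(((s - cfg.iso_peak_s) / cfg.iso_width) ** 2))
        return cfg.iso_scale * (cfg.iso_floor + bump)

    def variational(self, voxels) -> np.ndarray:
        """Band-limited random field, evaluated on the ASU representative so
        it is exactly symmetric over the Laue group."""
        cfg = self.config
        if cfg.var_amplitude == 0:
            return np.zeros(len(np.atleast_2d(voxels)))
        asu, _, _ = map_to_asu(np.atleast_2d(voxels), self.grid)
        x = voxel_center(asu, self.grid)
        phases = 2 * np.pi * (x @ self.var_dirs.T) + self.var_phases
        f = np.cos(phases) @ self.var_coefs
        return cfg.var_amplitude * f / np.sqrt(len(self.var_coefs))

    def halo(self, voxels) -> np.ndarray:
        """Inverse-square halo around allowed nodes, in fractional units.

        The offset magnitude is floored at the peak-mask radius so the value
        at a Bragg-containing voxel represents the measurable annulus just
        outside the mask.
        """
        cfg = self.config
        if cfg.halo_amplitude == 0:
            return np.zeros(len(np.atleast_2d(voxels)))
        frac = voxel_center(np.atleast_2d(voxels), self.grid)
        node = np.rint(frac).astype(np.int64)
        allowed = centering_allowed(node, cfg.centering)
        dq = np.linalg.norm(frac - node, axis=1)
        dq = np.maximum(dq, cfg.halo_mask_radius)
        return np.where(allowed, cfg.halo_amplitude / (dq**2 + cfg.halo_epsilon), 0.0)

    def intensity(self, voxels) -> np.ndarray:
        """True diffuse intensity I₀ per voxel (constant on Laue orbits)."""
        vox = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        s = s_magnitude(voxel_center(vox, self.grid), self.grid.cell)
        return self.isotropic(s) + self.variational(vox) + self.halo(vox)

    # -- artifact fields ----------------------------------------------------
    def b_field(self, phi, sweep: int) -> np.ndarray:
        cfg = self.config
        return 1.0 + cfg.amp_b * np.sin(
            2 * np.pi * np.asarray(phi, dtype=float) / cfg.phi_range
            + self.b_phases[sweep]
        )

    def a_field(self, x, y, phi, sweep: int) -> np.ndarray:
        cfg = self.config
        nx, ny = cfg.detector_shape
        u = np.asarray(x, dtype=float) / max(nx - 1, 1)
        v = np.asarray(y, dtype=float) / max(ny - 1, 1)
        ph = np.asarray(phi, dtype=float)
        return 1.0 + cfg.amp_a * np.sin(np.pi * u) * np.cos(np.pi * v) * np.cos(
            2 * np.pi * ph / cfg.phi_range + self.a_phases[sweep]
        )

    def c_field(self, s, phi, sweep: int) -> np.ndarray:
        """Offset truth; touches zero at the sweep ends so the positivity
        restraint leaves it identifiable."""
        cfg = self.config
        s = np.asarray(s, dtype=float)
        ph = np.asarray(phi, dtype=float)
        return (
            cfg.amp_c
            * self.c_scales[sweep]
            * np.exp(-s / 0.4)
            * np.sin(np.pi * ph / cfg.phi_range) ** 2
        )

    def d_field(self, x, y) -> np.ndarray:
        """Detector flat field: low-response chip rectangle plus panel-edge
        attenuation (3×3 panel layout, up to ``edge_drop`` at the edges)."""
        cfg = self.config
        nx, ny = cfg.detector_shape
        xf = np.asarray(x, dtype=float)
        yf = np.asarray(y, dtype=float)
        u = xf / max(nx - 1, 1)
        v = yf / max(ny - 1, 1)
        d = np.ones(np.broadcast(xf, yf).shape)
        chip = (u >= 0.60) & (u <= 0.75) & (v >= 0.10) & (v <= 0.20)
        d = d * np.where(chip, 1.0 - cfg.chip_drop, 1.0)
        # distance (pixels) to the nearest panel boundary of a 3x3 layout
        px = (xf * 3.0 / nx) % 1.0
        py = (yf * 3.0 / ny) % 1.0
        dist_x = np.minimum(px, 1.0 - px) * nx / 3.0
        dist_y = np.minimum(py, 1.0 - py) * ny / 3.0
        dist = np.minimum(dist_x, dist_y)
        d = d * (1.0 - cfg.edge_drop * np.exp(-dist / 20.0))
        return d

    def scales(self, obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """True per-observation (m, o) at the observation coordinates."""
        sweep_arr = obs["batch"].to_numpy()
        phi = obs["phi"].to_numpy(dtype=float)
        x = obs["x"].to_numpy(dtype=float)
        y = obs["y"].to_numpy(dtype=float)
        s = obs["s"].to_numpy(dtype=float)
        m = np.empty(len(obs))
        o = np.empty(len(obs))
        for sw in np.unique(sweep_arr):
            sel = sweep_arr == sw
            a = self.a_field(x[sel], y[sel], phi[sel], int(sw))
            b = self.b_field(phi[sel], int(sw))
            c = self.c_field(s[sel], phi[sel], int(sw))
            d = self.d_field(x[sel], y[sel])
            m[sel] = a * b * d
            o[sel] = a * c * d
        return m, o


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the deterministic truth fields for one experiment."""
    rng = _rng(config, 1)
    dirs = rng.normal(size=(config.var_n_waves, 3)) * 3.0
    phases = rng.uniform(0, 2 * np.pi, size=config.var_n_waves)
    coefs = rng.normal(size=config.var_n_waves)
    b_phases = rng.uniform(0, 2 * np.pi, size=config.n_sweeps)
    a_phases = rng.uniform(0, 2 * np.pi, size=config.n_sweeps)
    c_scales = rng.uniform(0.5, 1.0, size=config.n_sweeps)
    return GroundTruth(
        config=config,
        grid=config.make_grid(),
        var_dirs=dirs,
        var_phases=phases,
        var_coefs=coefs,
        b_phases=b_phases,
        a_phases=a_phases,
        c_scales=c_scales,
    )


def _sample_voxel_pool(truth: GroundTruth) -> np.ndarray:
    """Distinct voxels spread over the resolution range.

    Voxels centered on allowed integer nodes are kept: in the real pipeline
    the Bragg-containing voxel survives integration (only the pixels inside
    the peak mask are lost) and carries the halo signal.
    """
    cfg = truth.config
    grid = truth.grid
    rng = _rng(cfg, 2)
    want = cfg.n_voxels
    collected = np.empty((0, 3), dtype=np.int64)
    while len(collected) < want:
        n_draw = 6 * want
        u = rng.normal(size=(n_draw, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        s = np.cbrt(rng.uniform(cfg.s_min**3, cfg.s_max**3, size=n_draw))
        frac = u * (s * cfg.cell_a)[:, None]
        vox = voxel_of(frac, grid)
        collected = np.unique(np.concatenate([collected, vox]), axis=0)
    idx = rng.permutation(len(collected))[:want]
    return collected[idx]


def simulate_sweep(
    truth: GroundTruth, config: SimulationConfig, sweep: int, voxel_pool=None
) -> pd.DataFrame:
    """Simulate one rotation sweep at observation level.

    Each observation picks a voxel from the pool, applies a random Laue
    operator (so equivalents are revisited with multiplicity ≈
    obs_per_sweep/n_voxels per sweep), draws scan coordinates, and draws
    Poisson counts with expectation

        E[n] = Δt · [m·I₀ + o + r_bg] · (ΔΩ·E·A·P)

    with m = a·b·d and o = a·c·d evaluated from the truth fields.  The
    emitted table carries everything needed to invert the corrections
    (r_bg, the factor product) plus truth columns m_true, o_true, I0_true.
    """
    if voxel_pool is None:
        voxel_pool = _sample_voxel_pool(truth)
    grid = truth.grid
    rng = _rng(config, 3, sweep)
    n = config.obs_per_sweep
    pick = rng.integers(0, len(voxel_pool), size=n)
    ops = grid.laue_ops[rng.integers(0, len(grid.laue_ops), size=n)]
    vox = np.einsum("nij,nj->ni", ops, voxel_pool[pick])
    phi = rng.uniform(0.0, config.phi_range, size=n)
    nx, ny = config.detector_shape
    x = rng.uniform(0, nx - 1, size=n)
    y = rng.uniform(0, ny - 1, size=n)
    s = s_magnitude(voxel_center(vox, grid), grid.cell)
    dt = np.full(n, config.pixels_per_obs * config.exposure_per_frame)

    i0 = truth.intensity(vox)
    asu, _, friedel = map_to_asu(vox, grid)
    obs = pd.DataFrame(
        {
            "i": vox[:, 0],
            "j": vox[:, 1],
            "k": vox[:, 2],
            "key": pack_voxels(vox),
            "asu_key": pack_voxels(asu),
            "friedel": friedel,
            "n_pixels": config.pixels_per_obs,
            "phi": phi,
            "x": x,
            "y": y,
            "s": s,
            "dt": dt,
            "batch": sweep,
        }
    )
    m, o = truth.scales(obs)
    fprod = np.ones(n)
    rate = (m * i0 + o + config.background_rate) * fprod
    counts = rng.poisson(np.maximum(rate, 0.0) * dt)
    obs["n"] = counts
    obs["r_bg"] = config.background_rate * fprod
    obs["fprod"] = fprod
    obs["m_true"] = m
    obs["o_true"] = o
    obs["I0_true"] = i0
    return obs


def apply_corrections(obs: pd.DataFrame) -> pd.DataFrame:
    """Add corrected I and sigma columns using the emitted r_bg/factors."""
    factors = CorrectionFactors(solid_angle=obs["fprod"].to_numpy())
    I, sigma = correct_observation(
        obs["n"].to_numpy(),
        obs["dt"].to_numpy(dtype=float),
        obs["r_bg"].to_numpy(dtype=float),
        factors,
    )
    out = obs.copy()
    out["I"] = I
    out["sigma"] = sigma
    return out


def simulate_experiment(config: SimulationConfig):
    """Simulate all sweeps and apply corrections.

    Returns ``(obs, truth)`` where ``obs`` is the concatenated, corrected
    observation table for every sweep.
    """
    truth = simulate_truth(config)
    pool = _sample_voxel_pool(truth)
    tables = [
        simulate_sweep(truth, config, sweep, voxel_pool=pool)
        for sweep in range(config.n_sweeps)
    ]
    obs = pd.concat(tables, ignore_index=True)
    return apply_corrections(obs), truth


# ---------------------------------------------------------------------------
# image mode


_IMG_EX = np.array([0.021, 0.002, 0.0007])
_IMG_EY = np.array([0.0013, 0.019, 0.0011])
_IMG_EF = np.array([0.003, 0.0041, 0.023])
# places the allowed node (5,4,3) mid-detector around frame 10, so Bragg
# peaks are guaranteed inside even small test stacks
_IMG_ORIGIN = np.array([4.4348, 3.455, 2.7268])


def image_geometry(config: SimulationConfig, frames: int):
    """Synthetic per-pixel fractional-hkl geometry for image mode.

    A fixed, invertible linear map assigns each (frame, x, y) a fractional
    hkl; the detector spans a few reciprocal cells and the frame axis
    advances the pattern slowly, so Bragg nodes sweep across the images.
    Not a physical ray trace — a plumbing stand-in with the right
    statistical structure.
    """

    def hkl_of(frame, x, y):
        f = np.asarray(frame, dtype=float)[..., None]
        xx = np.asarray(x, dtype=float)[..., None]
        yy = np.asarray(y, dtype=float)[..., None]
        return _IMG_ORIGIN + xx * _IMG_EX + yy * _IMG_EY + f * _IMG_EF

    return hkl_of


def _inject_bragg_spikes(stack, config, rng, amplitude, sigma):
    """Add photon events drawn from ellipsoidal Gaussian Bragg peaks.

    Allowed nodes within the sampled reciprocal slab emit ``~Poisson(
    amplitude)`` photons each, positioned with isotropic spread ``sigma``
    (fractional hkl) and mapped back to (x, y, frame) through the inverse
    of the linear geometry.
    """
    frames, nx, ny = stack.shape
    basis = np.column_stack([_IMG_EX, _IMG_EY, _IMG_EF])
    inv = np.linalg.inv(basis)
    # bounding box of the sampled slab, padded by the peak extent
    corners = np.array(
        [
            _IMG_ORIGIN + x * _IMG_EX + y * _IMG_EY + f * _IMG_EF
            for x in (0, nx - 1)
            for y in (0, ny - 1)
            for f in (0, frames - 1)
        ]
    )
    lo = np.floor(corners.min(axis=0) - 4 * sigma).astype(int)
    hi = np.ceil(corners.max(axis=0) + 4 * sigma).astype(int)
    nodes = np.stack(
        np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    nodes = nodes[centering_allowed(nodes, config.centering)]
    for node in nodes:
        n_events = rng.poisson(amplitude)
        if n_events == 0:
            continue
        delta = rng.normal(0.0, sigma, size=(n_events, 3))
        xyz = (inv @ (node + delta - _IMG_ORIGIN).T).T
        pix = np.rint(xyz).astype(np.int64)
        keep = (
            (pix[:, 0] >= 0) & (pix[:, 0] < nx)
            & (pix[:, 1] >= 0) & (pix[:, 1] < ny)
            & (pix[:, 2] >= 0) & (pix[:, 2] < frames)
        )
        pix = pix[keep]
        np.add.at(stack, (pix[:, 2], pix[:, 0], pix[:, 1]), 1)


def simulate_images(
    config: SimulationConfig,
    frames: int = 60,
    bragg_amplitude: float = 2000.0,
    bragg_sigma: float = 0.02,
    background_only: bool = False,
):
    """Rasterize a small synthetic detector (image mode).

    Returns ``(stack, pixels, hkl_of)``: the (frames, nx, ny) photon-count
    stack, a tidy per-pixel DataFrame (frame, phi, x, y, count, h, k, l)
    and the geometry function.  With ``background_only`` the crystal is
    "moved out of the beam": only the background rate is recorded.
    """
    truth = simulate_truth(config)
    grid = truth.grid
    nx, ny = config.detector_shape
    hkl_of = image_geometry(config, frames)
    rng = _rng(config, 4, int(background_only))
    xs = np.arange(nx)
    ys = np.arange(ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    stack = np.empty((frames, nx, ny), dtype=np.int64)
    records = []
    dt = config.exposure_per_frame
    for f in range(frames):
        phi = f * config.dphi
        rate = np.full((nx, ny), config.background_rate, dtype=float)
        hkl = hkl_of(np.full(X.shape, f), X, Y)
        if not background_only:
            vox = voxel_of(hkl.reshape(-1, 3), grid)
            i0 = truth.intensity(vox)
            obs_like = pd.DataFrame(
                {
                    "batch": 0,
                    "phi": phi,
                    "x": X.ravel(),
                    "y": Y.ravel(),
                    "s": s_magnitude(hkl.reshape(-1, 3), grid.cell),
                }
            )
            m, o = truth.scales(obs_like)
            rate = rate + (m * i0 + o).reshape(nx, ny)
        counts = rng.poisson(rate * dt)
        stack[f] = counts
        records.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "phi": phi,
                    "x": X.ravel(),
                    "y": Y.ravel(),
                    "h": hkl[..., 0].ravel(),
                    "k": hkl[..., 1].ravel(),
                    "l": hkl[..., 2].ravel(),
                }
            )
        )
    if not background_only and bragg_amplitude > 0:
        _inject_bragg_spikes(stack, config, rng, bragg_amplitude, bragg_sigma)
    pixels = pd.concat(records, ignore_index=True)
    pixels["count"] = stack.reshape(len(pixels))
    return stack, pixels, hkl_of
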