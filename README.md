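# dsmap

Reciprocal-space mapping, scaling and merging of macromolecular **diffuse
scattering** from rotation-series X-ray diffraction data.

Diffuse scattering — the weak, continuous intensity between Bragg peaks —
encodes correlated atomic displacements in protein crystals. Measuring it
quantitatively requires reconstructing the full three-dimensional intensity
distribution on a grid of fractional Miller indices that oversamples the
reciprocal lattice, and correcting systematic errors that easily swamp the
few-percent variational signal of interest. `dsmap` implements the numerical
core of that workflow for researchers processing fine φ-sliced rotation data:

- **Voxel grid & symmetry** — any integer subdivision of the reciprocal cell;
  lattice-centering reflection conditions (e.g. *h*+*k*+*l* = 2*n* for I);
  Laue-group mapping to an asymmetric unit (m-3̄ preset: point group 23 closed
  under inversion, 24 operators).
- **Bragg masking** — strong-pixel search, empirical ellipsoidal Gaussian
  peak-shape fit in Δ*hkl*, 3σ masks at every predicted peak, outlier pixels
  flagged.
- **Integration & corrections** — chunk-invariant accumulation of photon
  counts per (voxel, sweep); binned background maps with multilinear lookup;
  *I* = (*n*/Δ*t* − *r*_bg)/(ΔΩ·*E*·*A*·*P*), σ = √*n*/Δ*t*/(ΔΩ·*E*·*A*·*P*).
- **Scaling & merging** — the four-parameter model
  *I*_pred = *a·d·*(*b·I*₀ + *c*) with absorption *a*(*x*,*y*,φ), illuminated
  volume *b*(φ), background offset *c*(*s*,φ) ≥ 0 and a global detector flat
  field *d*(*x*,*y*), each linearly interpolated from control-point grids and
  refined by regularized alternating least squares
  (‖**Ax** − **b**‖² + Σ λ‖**Bx**‖², second-derivative/Laplacian smoothness,
  REGALS-style α re-normalization); inverse-variance merging over Laue orbits.
- **Quality statistics** — CC₁/₂ (random half-sets), CC_Friedel
  (inversion-related halves) and CC_Rep (independent crystals) per resolution
  shell; halo/non-halo partition; shell means and standard deviations.
- **Maps** — symmetry expansion into dense 3-D arrays and isotropic
  (shell-mean) subtraction for visualizing weak variational features.
- **Simulator** — synthetic rotation series with Poisson counting, a diffuse
  profile peaking near 3 Å, inverse-square halos at allowed nodes, all four
  artifact fields and known ground truth, so every stage is testable
  end-to-end without experimental data.

## Worked example

Simulate a two-sweep experiment (100,000 observations, all four artifact
fields active), refine the full scaling model and check recovery against the
simulator's ground truth:

```python
import numpy as np
from dsmap import SimulationConfig, RefinementConfig, refine
from dsmap.simulator import simulate_experiment
from dsmap.merge_stats import make_shells, split_observations, cc_by_shell, halo_partition
from dsmap.scaling import merge_scaled

cfg = SimulationConfig(seed=1)            # 2 sweeps x 50,000 observations
obs, truth = simulate_experiment(cfg)     # corrected intensities + ground truth

model, merged, diag = refine(obs, RefinementConfig.full_model(d_nx=31, d_ny=31))
keep = ~diag["outlier"]
cc_m = np.corrcoef(diag["m"][keep], obs.m_true[keep])[0, 1]
print(f"cycles: {diag['cycles']}  chi2/obs: {diag['chi2_per_obs'][-1]:.3f}")
print(f"scale-factor recovery (Pearson r): {cc_m:.4f}")

halo = halo_partition(merged, cfg.make_grid())
print(f"merged voxels: {len(merged)}  halo/non-halo mean ratio: "
      f"{merged.I[halo].mean()/merged.I[~halo].mean():.2f}")

usable = obs.loc[keep & (obs.sigma > 0)]
shells = make_shells(merged.s, 10, mode="equal_count")
h1, h2 = split_observations(usable, "randomHalf", seed=1)
cc = cc_by_shell(merge_scaled(h1, model), merge_scaled(h2, model), shells)
print(f"CC1/2 per shell: {np.round(cc.cc.to_numpy(), 3)}")
```

Output:

```
cycles: 9  chi2/obs: 0.975
scale-factor recovery (Pearson r): 0.9940
merged voxels: 3988  halo/non-halo mean ratio: 4.68
CC1/2 per shell: [0.993 0.984 0.983 0.99  0.992 0.988 0.991 0.993 0.993 0.985]
```

The refinement converges in nine cycles to χ²/observation ≈ 1 (residuals at
the Poisson noise level). The fitted per-observation scale factors
*m* = *a·b·d* correlate with the simulator's truth at *r* = 0.994, merged
voxels centered on allowed reciprocal-lattice nodes ("halo" voxels) are ~4.7×
brighter than the rest, and the half-set correlation CC₁/₂ is ≥ 0.98 in every
resolution shell.

The same workflow is available from the shell, stage by stage, on a single
HDF5 project file:

```sh
dsmap simulate --out proj.h5 --seed 1
dsmap correct  proj.h5
dsmap scale    proj.h5 --full-model
dsmap merge    proj.h5 --split randomHalf --seed 1 --tsv merged.tsv
dsmap map      proj.h5 --bounds -6:6,-6:6,-6:6
dsmap stats    proj.h5
```

`dsmap simulate --mode images` additionally writes rasterized image stacks
(with Bragg spikes and a crystal-out-of-beam background stack) for the
`mask-peaks`, `bin-background` and `integrate` stages. Each subcommand
documents its options under `--help`.

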