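# Methods

This note documents the models, numerical choices and limitations behind
`dsmap`. It complements the API docstrings; nothing here is a measured
result — all quantitative claims are recomputed by the test suite and
`scripts/acceptance.py`.

## Reciprocal-space grid and symmetry

Diffuse intensity is accumulated on voxels whose centers lie at fractional
Miller indices (i/n_h, j/n_k, k/n_l) for integer subdivisions n per axis
(threefold oversampling by default). Pixels are assigned to the nearest
voxel; exact half-way ties round half to even on each axis independently,
which is deterministic and unbiased. Bragg ("halo") voxels are those whose
center is an integer hkl node passing the centering reflection condition
(P: all; I: h+k+l even; C: h+k even; F: h,k,l all even or all odd). For a
threefold-oversampled I-centered grid, exhaustive enumeration over one
centering period gives **53 diffuse voxels per Bragg peak** (2·3³ − 1); the
general closed form is (per-node multiplicity)·n³ − 1.

Laue groups are represented as explicit integer matrix lists, validated for
closure, identity and centrosymmetry. The m-3̄ preset is generated by
closing the point-group-23 generators and adjoining inversion (24
operators); it is cross-checked against gemmi's space-group tables in the
tests. The asymmetric-unit representative of a voxel is its
lexicographically greatest image under all operators — orbit-constant and
deterministic without crystallographic wedge tables. The Friedel flag
records whether the selected operator is improper (det = −1); ties between
operators giving the same image resolve to the lowest operator index with
the identity first, so representatives themselves are never flagged.

Scattering-vector magnitudes use the reciprocal metric tensor (inverse of
the direct metric), reducing to s = |hkl|/a for cubic cells; resolution is
1/s. The real-space wavelength of a lattice modulation at fractional offset
q from a node is a/q (cubic only).

## Corrections

Background stacks are binned by ceiling division (partial edge bins are
retained, so 2463 pixels binned by 20 give 124 bins), each cell holding the
mean rate over unmasked pixel-frames. Lookup uses multilinear interpolation
between bin centers, clamped at the edges (no extrapolation — background
varies slowly and extrapolation risks negative rates); invalid (fully
masked) cells are excluded by renormalizing interpolation weights, and a
fully invalid neighborhood yields NaN to flag the observation.

Corrected intensities are I = (n/Δt − r_bg)/(ΔΩ·E·A·P) with
σ = √n/Δt/(ΔΩ·E·A·P). The Poisson error of the binned background is
neglected (binning suppresses it). Zero-count observations get σ = 0 and
are excluded from inverse-variance merging rather than given an artificial
floor — the simplest faithful reading of the error model.

## Bragg masking

Strong pixels are those with counts strictly above the threshold (default
20 photons). Their offsets from the nearest integer node, wrapped to
[−0.5, 0.5) per component, form a point cloud to which a mean and sample
covariance are fitted (at least 10 points required; rank-deficient clouds
abort). Fitting the mean rather than pinning it at zero costs nothing for
unbiased geometry and absorbs small systematic offsets. One global peak
shape per data set is used. The mask covers every *predicted* peak — every
centering-allowed node — regardless of intensity, thresholding the
Mahalanobis distance at n_sigma (default 3, inclusive boundary); nodes that
are systematically absent are not masked. Strong pixels outside every
ellipsoid are flagged as outliers and excluded from integration.

## Integration

Accumulation per (voxel, sweep) tracks total counts, contributing pixels
and **unweighted** mean scan coordinates (φ, x, y): the coordinates
describe where the voxel was sampled, not where photons landed, and the
unweighted mean is robust at low counts. Cumulative exposure is
Δt = n_pixels × exposure per image. The accumulator is an associative,
commutative merge over stream chunks, so results are independent of
partitioning and worker count (counts are exact integer sums; coordinate
means agree to floating-point rounding, verified at 1e−12 relative).

## Scaling model and refinement

The model predicts each observation as I_pred = m·I₀ + o with m = a·b·d and
o = a·c·d:

| term | coordinates | meaning | regularizers |
|------|-------------|---------|--------------|
| a | x, y, φ | absorption | Laplacian (x,y), 2nd derivative (φ) |
| b | φ | illuminated volume | 2nd derivative (φ) |
| c | s, φ | background offset | 2nd derivatives (s, φ), identity |
| d | x, y | detector flat field | Laplacian (x,y) |

a, b, c are per sweep; d is global. Parameters live on uniform control-point
grids and are evaluated by sparse multilinear interpolation (rows sum to 1,
entries ≥ 0; queries clamp to the grid range). Defaults: b every 2.5° of φ;
c on 15 s-points × 5° of φ; a on 5×5 detector points × 10° of φ; d on
200×200 detector points. All are overridable; the tests and acceptance
script use a 31×31 flat-field grid on the simulator's 512-pixel detector,
roughly one control point per panel-edge attenuation length — the same
relative density as the 200×200 default on a real ~2500-pixel detector,
while avoiding needless parameters at desk scale.

Refinement alternates inverse-variance merging with one regularized linear
least-squares fit per parameter, in the order **b → c → a → d** (largest
effect first; the offset next so absorption and flat field fit residual
structure). Each fit solves the normal equations
(AᵀA + Σ λ_k B_kᵀB_k)x = Aᵀb by sparse direct factorization; a singular
system raises an error suggesting a larger α. Design matrices follow from
rearranging the residual with the partner factors fixed; for the offset the
target is (I − a∘b∘d∘I₀)/σ, the form consistent with
I_pred = a·d·(b·I₀ + c).

Regularization weights are re-normalized as λ = α·‖A‖²_F/‖B‖²_F so a given
α behaves comparably across grid sizes, data volumes and noise levels.
Because the mean diagonal of AᵀA equals ‖A‖²_F/n_params, an *identity*
penalty under this normalization shrinks the solution by a factor
≈ 1/(1+α) independent of the data volume. The smoothness terms therefore
use α = 1 (curvature suppressed at the noise level, null spaces — affine
and planar fields — untouched), while the offset-magnitude penalty uses
α = 0.01: large enough to pin the direction left degenerate by the
offset/merged-intensity trade-off, small enough (1% shrinkage) not to bias
the recovered offset.

The offset positivity restraint is applied after each c fit: negative
control values clip to zero; if all are positive, a constant is subtracted
so the minimum is zero. Combined with the magnitude penalty this resolves
the gauge freedom c → c − ψ(s), I₀ → I₀ + ψ(s): any positive ψ would drive
the offset negative wherever the true offset vanishes.

Gauge fixing sets the mean of all b control values across sweeps to 1 after
each cycle (the compensating factor is absorbed by the next merge).
Outliers with scaled residuals beyond 5σ are removed after each cycle.
Iteration halts when χ² per observation changes by less than 1e−4
(relative) or after 20 cycles; three consecutive χ² increases abort with
diagnostics. χ² is flat along the offset gauge direction, so offset-heavy
problems typically use most of their cycles while the positivity restraint
walks the degenerate component out of I₀.

## Merging, splits and statistics

Observations are inverse-scaled (I_scaled = (I − o)/m, σ_scaled = σ/m) and
averaged per ASU voxel with weights σ_scaled⁻²; σ₀ = (Σw)^(−1/2). Voxels
with no usable observation are absent from the output rather than zero.

Random half-sets shuffle each voxel's observations with a seeded generator
and assign them alternately, starting with a per-voxel fair coin, so
per-voxel imbalance is at most one and odd counts balance across voxels.
The Friedel split uses the improper-operator flag. Per-shell Pearson
correlations over commonly observed voxels define CC₁/₂, CC_Friedel and
(between disjoint, independently scaled batch groups) CC_Rep; shells with
fewer than three common voxels report NaN, never zero. Shells are
equal-width in s by default; equal-count (quantile) shells are provided and
preferred for correlation statistics, which are unstable in sparsely
populated shells. Shell means and standard deviations are normalized by a
single constant, the maximum over shells of the non-halo mean.

Maps are filled by symmetry expansion (every voxel takes its ASU
representative's value; unobserved voxels are NaN so plots can distinguish
"missing" from "zero"). The isotropic component is the per-shell mean of
*non-halo* voxels — halo voxels would bias it upward — interpolated
linearly in s between shell centers and clamped at the ends.

## Simulator

The simulator defines the study conditions for all tests: a cubic
a = 79.48 Å cell, I centering, Laue group m-3̄, threefold oversampling, two
50° sweeps at 0.1°/frame and 0.1 s/frame, 50,000 observations per sweep
drawn from a pool of 4,000 distinct voxels between s = 0.05 and 0.7 Å⁻¹
(multiplicity ≈ 25, in the spirit of modern high-redundancy collection),
50 pixels per observation, and a 512×512-pixel abstract detector.

The true intensity is I₀ = isotropic + variational + halo: a smooth bump
peaking at s = 0.33 Å⁻¹ (≈3 Å, the solvent-dominated maximum typical of
protein crystals) over a floor, scale 20 photons s⁻¹; a band-limited random
cosine field (amplitude 1, i.e. ~5% of the peak) evaluated on the ASU
representative so it is exactly Laue-symmetric; and a halo
A/(Δq² + ε) at centering-allowed nodes (A = 0.5, ε = 0.005 in fractional
units), with the offset magnitude floored at the 0.102 peak-mask radius so
the value at a Bragg-containing voxel represents the measurable annulus
outside the mask. Artifact fields mirror the scaling model: b(φ) a ±30%
sinusoid; a(x,y,φ) a ±10% smooth field (absorption-scale variation);
c(s,φ) a positive offset (amplitude 3) decaying in s and vanishing at the
sweep ends, so the positivity restraint leaves it identifiable; d(x,y) a
flat field with a 15%-low chip rectangle and panel-edge attenuation up to
20% (3×3 panel layout, 20-pixel decay). Expected counts are
Δt·[m·I₀ + o + r_bg]·(ΔΩ·E·A·P) with Poisson draws; the emitted tables
carry r_bg and the factor product so corrections can be inverted exactly,
plus ground-truth columns for validation.

Observation mode assigns fractional Miller indices directly (no ray
tracing); geometry errors, beam divergence, mosaic spread, energy bandwidth
and radiation damage are not modeled. Image mode rasterizes a small
detector through a fixed invertible linear (frame, x, y) → hkl map and
injects Bragg peaks by drawing photon events from ellipsoidal Gaussians at
allowed nodes, mapped back through the inverse geometry — enough structure
to exercise peak fitting, masking, background binning and integration, but
not a physical diffraction model. Consequently, passing tests demonstrate
the correctness of the numerics (grid assignment, masking logic, operator
algebra, refinement convergence, statistics), not robustness to geometry
refinement errors or detector physics; those enter real data upstream of
this package.

All randomness flows from one seed; per-sweep and per-purpose substreams
are derived deterministically, so identical configurations reproduce
byte-identical outputs.

## Problem sizes

The test suite and acceptance script run the simulator at its default
conditions (10⁵ observations) for recovery and split statistics, with the
31×31 flat-field grid noted above; quick unit fixtures use 6,000–12,000
observations. Parameter-recovery checks compare recovered and true
*per-observation* values (Pearson r), which is well defined at any grid
resolution and invariant to the residual overall-scale gauge.

## Known limitations

- Absolute intensity scaling and Compton corrections are out of scope; all
  intensities are on an arbitrary common scale.
- Geometric correction factors (ΔΩ, E, A, P) are accepted as inputs, not
  computed from beamline metadata.
- The file schema is plain HDF5 with NeXus-style naming, not validated
  NeXus.
- The refinement assumes scale factors stay positive; no explicit
  positivity restraint is placed on a, b or d (none proved necessary under
  the study conditions).
- `--nproc` parallelizes integration chunk accumulation; refinement is
  single-threaded sparse algebra.
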