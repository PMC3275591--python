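# Methods

This document records the models, the default parameters (with units and
the reasoning behind each), and the known limits of what the synthetic
phantom does and does not emulate.

## Signal model and tensor fit

Each voxel follows the single-tensor diffusion model

```
S_k = S0 · exp(−b_k · g_kᵀ D g_k)
```

with `b_k` in s/mm², unit gradient direction `g_k`, and a symmetric
positive-semidefinite 3×3 tensor `D` in mm²/s. The fit linearizes by
taking logs: each measurement contributes the design row

```
[−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz, 1]
```

against `log S`, solved by ordinary least squares (default) or weighted
least squares with weights `S_k²` (the first-order variance of a
log-transformed signal). Voxels with any non-positive signal are excluded
(the log is undefined); negative eigenvalues are clamped to zero by
default and counted, or the voxel can be dropped instead. A rank-deficient
design (collinear directions) is an error, not a warning.

Scalar maps, from the sorted eigenvalues `λ1 ≥ λ2 ≥ λ3`:

- ADC (mean diffusivity): `(λ1+λ2+λ3)/3`
- axial `λ1`, radial `(λ2+λ3)/2`
- FA: `sqrt(3/2) · ‖λ − λ̄‖ / ‖λ‖`
- Westin shape coefficients, trace-normalized so they sum to exactly 1:
  `cl = (λ1−λ2)/T`, `cp = 2(λ2−λ3)/T`, `cs = 3λ3/T` with `T = λ1+λ2+λ3`.

## Gradient schemes

Single shell (default `b = 3000 s/mm²`, matching long-TE ex vivo
protocols) plus one `b = 0` volume. Directions are the spherical Fibonacci
point set — deterministic and near-uniform; a true electrostatic repulsion
layout would change the fit conditioning only marginally. One caveat found
while testing: the **6-point** Fibonacci layout happens to lie on a
quadric, so its design matrix is singular; the fit refuses it. Use ≥ 7
directions (the default scheme is 30).

## Brain masking

Segmentation runs on the isotropic DWI (iDWI), the mean of the `b > 0`
channels, which has much higher SNR than a single direction and no bright
b=0 CSF. Steps: min-max normalize, threshold at 5% of the maximum,
morphological **opening** (removes noise speckle; done first so the
closing cannot fuse speckle onto the brain boundary), morphological
**closing** (fills interior dropouts), keep the largest 26-connected
component. Brain volume is voxel count × voxel volume.

## Statistics

Group comparisons use a normality-gated test, mirroring common practice in
small-animal studies: both samples are tested with Shapiro-Francia W'
(Blom scores, Royston's p approximation); if both pass at α = 0.05 and
n ≥ 5 per group, a pooled-variance two-sided t-test is used, otherwise the
Mann-Whitney U. The Mann-Whitney p is **exact** for small samples
(n ≤ 9 per group): the two-sided deviation probability
`P(|R1 − E[R1]| ≥ observed)` computed by dynamic programming over doubled
midranks, which is valid under ties and matches brute-force enumeration
bit-for-bit. Spearman correlations use midranks with pairwise deletion of
missing scores.

## Voxel-based analysis

Registration is a contract: every subject supplies either nothing (shared
grid), a 4×4 voxel-space affine, a dense displacement field, or a
transform estimated by the internal Mattes mutual-information affine
registration (SimpleITK). Resampled maps are smoothed with a truncated
3×3×3 Gaussian (σ = 1 voxel) whose weights are renormalized over in-mask
neighbours, so background zeros never dilute edge voxels and a constant
map stays constant. Per voxel: a pooled-variance two-sided t-test between
groups, or Spearman correlation against a behavioral item, with
uncorrected significance masks at p < 0.01 and p < 0.05.

Because the template choice biases single-template results, the analysis
is repeated with each of several subjects as template and only voxels
flagged consistently (strict intersection by default) are reported. Under
the null this consensus strictly shrinks the flagged set; with the default
focal effect it recovers the effect region with Dice ≈ 1 at n = 10/10.

## The phantom

Geometry (default 32³ grid, 0.35 mm isotropic voxels): an ellipsoidal
"brain" of mildly anisotropic gray matter containing two cylindrical
white-matter tracts with orthogonal orientations (x and y). Tissue
calibration targets the magnitudes reported for fixed perinatal rabbit
brain: GM ADC 0.44e-3 mm²/s at FA 0.14, WM ADC 0.42e-3 mm²/s at FA 0.28;
with ~14% of brain voxels in tracts the whole-brain mean FA is 0.160
(control) and 0.150 (IUGR), and the FA > 0.2 masked mean sits near
0.27–0.28.

Group effect: the IUGR group loses FA by a programmed ΔFA per region
(default: 0.008 diffusely, 0.025 in the x tract; the focal spec puts 0.03
in the x tract only). The reduction is realized by **trace-preserving
deviatoric scaling** of the eigenvalues — λ1 falls while λ2, λ3 rise — so
the effect appears in FA and the Westin coefficients but, by construction,
not in ADC. This matches the empirical pattern of anisotropy differences
without diffusivity differences.

Between-subject variance has two components, both in FA:

- a **global multiplicative factor** per subject, relative SD 0.04, shared
  by every region (diffuse maturation differences; this dominates the
  whole-brain FA spread, giving a between-subject SD ≈ 0.016, i.e. "0.02"
  at two decimals);
- a small **per-region additive jitter** (SD 0.0165 in GM, 0.005 in WM;
  WM is kept nearly deterministic because FA-threshold-masked WM means are
  observed to vary very little between animals).

ADC varies through an independent global trace factor (relative SD 0.18).
Each region's per-subject FA target is realized exactly (clipped to the
feasible range of deviatoric scaling), so the generator's ground truth is
known in closed form; `generate_ground_truth` reproduces the full
generator's region values without building voxel arrays, which makes
Monte-Carlo calibration checks cheap.

Noise is Rician (magnitude of a complex Gaussian, scale 1% of S0 by
default) or optionally plain Gaussian. Birth weights are drawn per group
(control 47.0 ± 9.3 g, IUGR 30.4 ± 12.2 g). Behavioral scores: thirteen
items; the "head turn" item is coupled to the x tract's true FA through a
Gaussian copula with latent correlation 0.65, then discretized to the 0–3
item scale. Discretization and the region-versus-WM-mask mismatch
attenuate the recoverable Spearman correlation to roughly 0.45–0.55 at
n = 20.

## What the phantom does not emulate

- **Westin coefficient means.** Published global means of the shape
  coefficients (cl ≈ 0.16, cp ≈ 0.10, cs ≈ 0.74) cannot be reproduced by
  any single-tensor phantom whose FA matches 0.16: for trace-normalized
  coefficients those three numbers are mutually inconsistent with the FA
  they accompany. The phantom's prolate tensors give cl ≈ 0.09,
  cp ≈ 0.02, cs ≈ 0.90 at the same FA — the coefficients behave correctly
  (cl/cp fall and cs rises under the group effect), but their absolute
  levels reflect the idealized geometry, not real tissue heterogeneity.
- No partial-volume mixing, crossing fibers, or intra-voxel orientation
  dispersion; each region is a single tensor population.
- No susceptibility distortion, eddy currents, motion, or bias fields;
  subjects share one grid, so identity registration is exact and affine
  registration only has to undo itself.
- The internal registration is affine-only; elastic warping must be
  supplied externally as a displacement field.
- Voxel-wise p-values are uncorrected by design (consensus across
  templates is the replication device); no cluster or FDR correction is
  implemented.
- Rician noise is simulated at moderately high SNR; the fit does not
  include a Rician bias correction.
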