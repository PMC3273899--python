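# Methods

## Scope and model

`laminaq` quantifies the three-dimensional shape of the nuclear lamina — the
lamin meshwork lining the inner nuclear membrane — from confocal Z-stacks of
single nuclei, and classifies cell populations (fresh vs senescent vs
apoptotic-like, young- vs old-donor myoblasts, lamin mutants) from three
per-cell descriptors:

- **intensity** — mean lamina intensity normalised by the whole-nucleus mean,
- **skewness** — third standardised moment of the lamina intensity
  distribution,
- **curvature** — area-weighted mean absolute Gaussian curvature of the
  lamina surface, normalised so a sphere scores exactly 1.

The premise is biological: senescence redistributes lamin A out of a smooth
elliptical envelope (lowering normalised shell intensity, changing skewness),
and folding/blebbing of the envelope in apoptotic and mutant cells raises the
curvature descriptor. A linear discriminant on these three numbers separates
the populations; performance is reported as the leave-one-out (LOO)
cross-validated error with its binomial standard deviation, and significance
by label permutation.

## Pipeline stages and key choices

### Resampling (`stack_io`)

Confocal stacks are anisotropic (axial sampling 122 nm/voxel vs 40–60 nm
laterally at the reference acquisition settings). All geometry assumes an
isotropic grid, so stacks are resampled first. Choices:

- third-order spline interpolation: smooth shells; nearest/linear leave
  staircase artifacts that corrupt curvature;
- default isotropic target = the smallest input spacing (upsample z rather
  than degrade x/y), because curvature estimation is resolution-sensitive;
- spline overshoot below zero is clipped (intensities are counts);
- axis order (z, y, x), voxel-centred 0-based coordinates, spacings in nm.

Guarantees tested: constant images resample exactly; integrated intensity ×
voxel volume conserved within 1% on smooth shells; idempotence at fixed
target.

### Segmentation (`segmentation`)

Pipeline: Gaussian smooth (default sigma 100 nm) → global threshold → largest
connected component → morphological closing → hole fill (filled nucleus mask)
→ marching-cubes iso-surface of the mask boundary → mesh cleanup. A cell is
declared *unsegmentable* (and is excluded by callers, never silently patched)
when the component touches the stack border, the filled volume is below
`min_volume` (default 50 µm³ — the scale of a real nucleus; synthetic
configs pass 5 µm³, see below), or the mesh is not a closed genus-0
2-manifold (watertight, Euler characteristic 2). That triple check
operationalises "the lamina contour was not completely found".

Threshold choice. The default is the **upper threshold of a three-class
multi-Otsu** split (background / nucleoplasm / lamina). Two-class Otsu is
dominated by the dark background class and lands the binarisation boundary
well off the shell edge: on noiseless synthetic spheres it inflates the
enclosed volume by ~4% and by ~18% under shot noise, while the multi-Otsu
upper threshold sits near the half-maximum of the blurred shell edge
(−1.0%/+0.9% under the same conditions). When bright hotspot patches form a
fourth intensity class the upper split can land between shell and hotspot,
keeping only the patches; this is detected by a collapse (>50%) of the
enclosed volume relative to the permissive threshold, and the sub-histogram
below the hotspot class is re-split. Two-class Otsu and absolute thresholds
remain selectable.

Topology rescue. Deeply folded shells can leave tunnels through the filled
mask (the mesh comes out genus > 0). The closing step is escalated
deterministically (1×, 2×, 3× the configured iterations) before the cell is
declared unsegmentable. The mesh is extracted from a lightly smoothed mask
indicator at level 0.5, which attenuates voxel staircase at extraction time;
vertex intensities are sampled from the raw (pre-smoothing) stack.

### Features (`features`)

- *Intensity normalisation* divides per-vertex raw intensity by the mean over
  the **filled nucleus mask** (shell + interior). This makes the feature
  invariant to expression level and exposure, and it decreases when lamin
  redistributes into the nucleoplasm or intranuclear bodies — exactly the
  senescence phenotype the descriptor must track.
- *Skewness* uses the biased moment ratio g1 = m3/m2^{3/2}; the difference
  from the bias-corrected form is negligible at per-cell vertex counts
  (≥10³) and the plain ratio is the simpler convention. It is affine
  invariant by construction.
- *Gaussian curvature* is estimated by a local quadric fit: the neighbourhood
  of each vertex (default radius 3 mean edge lengths) is projected into the
  tangent frame of the area-weighted vertex normal, z = (ax² + 2bxy + cy²)/2
  + dx + ey is fit by least squares, and K = (ac − b²)/(1 + d² + e²)². On
  ≥5k-vertex analytic meshes the median relative error is ~0.5% for spheres
  and ellipsoids; the signed total curvature reproduces the Gauss–Bonnet
  value 4π within 2%, which is the estimator's built-in sanity check.
- *Curvature normalisation* multiplies the area-weighted mean |K| by R_eq²,
  R_eq = (3V/4π)^{1/3}. This makes the feature dimensionless and invariant
  to uniform spatial rescaling and anchors the sphere at exactly 1.
- Segmentation-derived meshes are Taubin-smoothed (10 passes) before
  curvature estimation to suppress residual voxelisation noise; analytic
  meshes are used as-is. On very dense meshes curvature is evaluated on an
  8000-vertex uniform subsample and averaged with barycentric area weights
  (one third of incident face areas), which caps cost without biasing the
  area-weighted mean.

### Classification (`classification`)

- Fisher LDA with pooled within-class covariance, ridge-regularised by
  1e-6·trace for near-singular cases. Multiclass by pairwise majority vote;
  vote ties are broken by smallest Mahalanobis distance to the class mean
  (pooled covariance), with lowest class index as a final deterministic
  fallback. Mahalanobis was preferred over a bare lowest-index rule because
  it uses the same metric the discriminant already assumes and removes the
  arbitrary dependence on label ordering except in exact ties.
- Features are z-scored **within every training fold** (default on,
  switchable) so the raw intensity scale cannot dominate and no test-cell
  statistics leak into training.
- LOO CV: each cell is classified by a discriminant trained on the other
  N−1; all cells are included — no outlier removal.
- The ± on the error is the binomial SD sqrt(e(1−e)/N). At N = 68 this
  reproduces the conventional printed pairs 6.1% ± 2.9% and 13% ± 4.1%.
- Significance: label-permutation test, p = (1 + #{permuted LOO error ≤
  observed})/(1 + n_perm), default n_perm = 999 (tests use 99–199). A
  one-sided binomial test against the majority-class chance level is attached
  as a secondary report. The permutation test's type-I rate is checked
  against nominal over replicate null datasets.
- Calibration: on equal-covariance Gaussian populations the LOO error is
  required to sit within 3 binomial SD of the analytic Bayes error
  Φ(−Δ/2) at N = 200.

### FRAP (`frap`)

Double normalisation cancels background and any fading shared by the bleach
ROI and the unbleached reference; the pre-bleach level is 1 by construction.
Recovery is fitted with a single exponential I(t) = I0 + A(1 − e^{−t/τ}) on
the post-bleach frames — the minimal model yielding both reported
quantities, T/2 = τ ln 2 and immobile fraction = 1 − (plateau −
I_bleach)/(1 − I_bleach), with I_bleach the first post-bleach value. A
model-free half-time (first crossing of the midpoint between I_bleach and the
mean of the last 30 frames) is attached as a cross-check. Group comparison is
the two-sample Student t-test (equal variance by default, Welch by flag).
The simulator reproduces the acquisition protocol: 10 pre- and 300
post-bleach frames at 0.555 s intervals.

## The synthetic-data generator

No raw image data are deposited with the reference experiments, so every
stage is validated on simulated nuclei with analytic ground truth. A nucleus
is a star-shaped radial surface r(θ,φ) = r_ellipsoid · (1 + wrinkles +
blebs):

- wrinkles: random real spherical-harmonic field, degrees 2..L with equal
  expected power per degree, scaled to a target RMS amplitude — smooth,
  band-limited roughness whose strength and scale are controlled;
- blebs: Gaussian radial bumps at random directions (local protrusions of
  apoptotic/mutant nuclei);
- hotspots: contiguous spherical-cap patches of elevated shell intensity
  (spatially coherent lamin accumulation, not salt-and-pepper);
- curvature ground truth: closed form for unperturbed ellipsoids, finite
  differences of the fundamental forms on the parametric grid otherwise;
  Gauss–Bonnet closes within 1% for ellipsoids and within ~3% for the most
  strongly folded template (finite-difference quadrature error grows with
  fold depth).

Imaging model: anisotropic Gaussian blur (default sigma 250 nm axial /
100 nm lateral), Poisson shot noise at a photon scale, Gaussian read noise,
constant background. All randomness flows through explicit seeds; identical
seeds give bit-identical stacks.

Phenotype templates (the simulated study conditions):

| template   | semiaxes (nm)    | wrinkle amp | L  | blebs | hotspots        | shell:nucleoplasm |
|------------|------------------|-------------|----|-------|-----------------|-------------------|
| fresh      | 2200, 1900, 1400 | 0.01        | 4  | 0     | none            | 5                 |
| senescent  | 2100, 1800, 1500 | 0.08        | 8  | 0     | 20%, gain 2.0   | 3                 |
| apoptotic  | 1600, 1400, 1200 | 0.16        | 10 | 4     | 10%, gain 1.6   | 3                 |

The wrinkle/hotspot values for the senescent template and the fresh baseline
follow the intended contrast (smooth ellipsoid vs wrinkled shell with local
accumulation); the remaining numbers are fixed once at values that give
realistic-looking shells within a 6.4 µm field of view. Per-cell parameters
are jittered multiplicatively (relative sd 0.1, draws clipped at 1.5 sigma so
cells always fit the field). Nuclei are simulated at roughly half real linear
scale (volumes 7–35 µm³ instead of 100+ µm³) so a cell fits a 128³ grid at
50 nm isotropic spacing and the full pipeline runs in ~1–3 s per cell; the
features are scale-invariant by design, so this changes compute cost, not
the statistics being tested. Consequently synthetic configurations pass
`min_volume` = 5 µm³ to the segmentation gate whose real-data default is
50 µm³.

What the simulator does **not** emulate: a physically rigorous confocal PSF,
chromatin texture, intranuclear lamin bodies as separate objects, multiple
nuclei per field, optical aberrations, or fixation artifacts. Passing tests
therefore demonstrate correctness of the geometry, statistics, and pipeline
plumbing under controlled conditions — not performance on any specific real
microscope's data.

## Problem sizes used in the shipped validation

The validation suite and the reproduction script use: 10242-vertex meshes for
the curvature oracle; a 61-cell simulated cohort (14 fresh, 31 senescent, 14
apoptotic, plus 2 apoptotic-template cells planted into the senescent cohort
to form a 33-cell population with ~6% contamination); N = 200 for the Bayes
calibration; 50 replicates for the permutation type-I check; 20 seeds for
the noisy FRAP recovery. These sizes were chosen so the whole suite completes
in minutes on one CPU while keeping every statistical check inside
meaningful tolerance bands.

## Numerical details and degenerate inputs

- Parametric grids: 180 × 360 midpoint grid in (θ, φ); pole handling by
  antipodal φ-shift padding; all surface integrals by midpoint quadrature.
- Surfaces whose perturbation drives the radius below 20% of the smallest
  semi-axis are rejected as self-intersecting; the population simulator
  retries such draws deterministically (at most 5 times).
- Quadric fits with fewer than 7 neighbourhood points return NaN and are
  excluded from the area-weighted mean; a neighbourhood radius below 2 mean
  edge lengths is an error.
- Zero-variance intensity distributions make skewness undefined (error, not
  NaN); an empty nucleus mask or zero mask mean is an error.
- FRAP fits bound A ≥ 0 and τ > 0; a fitted plateau below the bleach level
  is reported as a failed fit. Traces where the reference does not exceed
  background at every frame are rejected.
- The segmentation success flag is deterministic for fixed input and
  parameters; sub-threshold constant background does not change the mask.

## Known limitations

- Absolute feature values depend on the stated normalisation conventions
  (whole-nucleus mean; R_eq²); other conventions differ by monotone
  per-feature transforms, which leave linear separability and LOO errors
  essentially unchanged but make axis values non-comparable across tools.
- The curvature estimator needs ≥ roughly 5k vertices per nucleus for the
  quoted accuracy; very coarse meshes degrade gracefully but measurably.
- Intensity skewness on segmentation-derived meshes reflects boundary
  sub-voxel sampling as well as true lamina texture; on synthetic data its
  population direction is therefore less stable than intensity or curvature.
- The single-exponential FRAP model is deliberately minimal; diffusion-type
  models with spot-size dependence are out of scope, and τ from poorly
  converged recoveries (plateau far beyond the recorded window) is
  extrapolated.
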