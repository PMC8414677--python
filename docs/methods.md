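# Methods

## Scope and data model

`mcshape` analyzes binary segmentation masks of the Meckel cave (MC), one
per side per subject, on regular anisotropic grids. Masks are NIfTI-1
files; the in-memory grid convention is axis order (slice, row, column),
0-based voxel-center indexing, physical position `origin + index * spacing`
in mm. The loader maps NIfTI storage order (i, j, k) onto this convention
once at read time and the writer inverts it, so round-trips are bit-exact.
Any nonzero label value counts as occupied, which tolerates the differing
label conventions of segmentation exporters. Rotated (oblique) affines are
rejected with an explicit error instead of being resampled: resampling
changes every shape feature, and a silent change is worse than a refusal.

Upstream steps — MRI acquisition, DICOM conversion, registration, manual
segmentation — are out of scope; the package starts at the finished mask.

## Feature definitions and numerical choices

The ten features follow the standard shape-radiomics definitions (see
README for formulas). Numerical decisions that the definitions leave open:

* **Mesh construction.** The isosurface is marching cubes at level 0.5 on
  the occupancy grid, padded with empty layers so boundary-touching ROIs
  still close. The raw binary indicator, however, produces a staircase
  surface whose area over-estimates a smooth boundary by roughly 8% at
  *any* resolution (and whose corner vertices inflate the Feret diameter
  by about half a voxel per side). The grid is therefore Gaussian-smoothed
  with sigma = 1 voxel per axis before triangulation; the 0.5 level set of
  the smoothed indicator tracks the true boundary closely (sphere test:
  area −0.5%, diameter +0.7% at 0.5 mm spacing) while preserving topology.
  For ROIs so thin or small that the smoothed field never reaches 0.5
  (single voxels, single slices), the raw binary grid is meshed instead,
  which keeps the mesh closed and the area positive. Meshes are checked
  closed (every edge shared by exactly two triangles) in the test suite.
* **Covariance convention.** Axis lengths use the population covariance
  (divide by N) of occupied voxel centers with uniform weights. This is
  the conventional radiomics definition and yields exactly 0 for the least
  axis of a single-slice segmentation. Eigenvalues are labelled by sorted
  magnitude (major = largest). Negative eigenvalues from floating-point
  noise are clamped to zero below 1e−12 before the square root; genuinely
  negative values raise.
* **Degenerate inputs.** Empty masks raise `empty ROI`; single-voxel masks
  return zero axis lengths with a warning and NaN flatness; diameter
  computations on coplanar vertex sets fall back from the 3D convex hull
  to the full point set.
* **Feret diameter.** Computed as the maximum pairwise distance over
  convex-hull vertices — equal to the all-pairs maximum, since the
  farthest pair of any set lies on its hull — and verified against the
  O(n²) brute force in the tests.
* **Anisotropy.** All geometry is done in physical mm after loading; no
  resampling ever occurs. The mesh anti-aliasing sigma is specified in
  voxels per axis, so strongly anisotropic grids are smoothed
  anisotropically in mm; at the near-isotropic spacings this package
  targets the effect is negligible.

Only the ten features above are computed; sphericity and elongation,
sometimes included in shape-radiomics panels, are out of scope.

## Synthetic cohort generator

The generator stands in for the study's MRI cohort, which is not publicly
deposited. Phantom family: solid ellipsoids with semi-axes a ≥ b ≥ c,
random rotation, discretized at voxel centers, with optional radial
boundary jitter (zero-mean Gaussian in mm, applied per voxel to the
implicit level function). A real MC is closer to an "open three-fingered
glove" than an ellipsoid, but only the size and flatness statistics feed
the downstream analysis, so ellipsoids with matched feature envelopes
suffice — passing tests demonstrate the pipeline's statistical behaviour,
not anatomical realism of the phantoms.

Flatness is controlled exactly through c/a (continuum identity
flatness = c/a for a uniform solid ellipsoid) with b = sqrt(ac); volume
through abc. Cohort defaults are the published study design:

| parameter | default | rationale |
|---|---|---|
| n_ptn / n_hc | 115 / 46 | study case numbers |
| p_right_affected | 77/115 | observed laterality |
| flatness means left/right | 0.41 / 0.39 | observed side means |
| affected_flatness_delta | 0.02 | observed affected–unaffected gap |
| between_subject_sd | 0.06 | observed flatness SD |
| left_right_correlation | 0.5 | not reported; exposed as a parameter |
| volume_range (mm³) | 94.23 – 1589.90 | observed envelope, log-uniform |
| flatness_range | 0.25 – 0.54 | observed envelope (truncation by redraw) |
| NVC pattern frequencies | 12/4/13/9 of 38; 34/9/25/9 of 77 | observed cross-tab |
| spacing | 0.5 mm isotropic | ~1 mm-slice imaging, sub-voxel modelling |

Ages and sexes are drawn to match the published demographics (PTN
62.89 ± 10.43 y, 70/115 female; HC 49.28 ± 10.96 y, 31/46 female). NVC is
metadata only: it never alters geometry beyond the configured delta
assignment, because the study reports flatness effects *within* NVC
strata, not NVC-caused geometry. The within-subject left–right correlation
(0.5) applies to both flatness and volume via a shared Gaussian factor
(Gaussian copula for the log-uniform volumes); no study value exists, so
it is a free parameter, not an assertion.

Each subject consumes an independent `numpy` substream seeded by
`(cohort_seed, subject_index)`, so enlarging a cohort reproduces earlier
subjects exactly; same seed means byte-identical truth tables and masks.
Infeasible flatness draws (outside `flatness_range`) are redrawn up to 100
times, then raise.

Generator fidelity, verified in the tests: extracted flatness tracks the
drawn target with mean absolute deviation < 0.01 at 0.5 mm spacing;
extracted volumes are within 3% of target.

## Statistical battery

All tests are two-sided at alpha = 0.05. Choices where the analysis plan
was open:

* Side contrasts are **paired** t-tests (both sides come from the same
  subject); an unpaired route exists via the group-comparison selectors.
* "Linear regression" group contrasts are OLS on a group indicator with no
  covariates — numerically the pooled two-sample t-test — with a Welch
  flag for unequal variances. No age/sex adjustment is performed.
* The laterality test is the exact two-sided binomial against 0.5, not a
  normal approximation (n = 115 is cheap to enumerate).
* Kendall correlation uses tau-b (tie-corrected), since rounded feature
  values tie.
* Chi-square on the 2×2 sex table is Pearson without continuity
  correction by default; a Yates flag exists.
* No multiple-testing correction by default (ten features tested
  marginally); Holm adjustment is available via `--holm` and adds a
  `p_holm` column.
* Degenerate strata are flagged, never silently dropped: fewer than three
  pairs, zero-variance differences, or constant features yield NaN
  p-values with a note.

Raw p-values are always reported; thresholding is left to the reader.

## Calibration and recovery study design

Two simulation studies characterize the pipeline (run by both the test
suite and `scripts/acceptance.py`):

* **Type-I calibration** — 500 cohorts of 30 patients under a *symmetric*
  null: `null_cohort_spec()` sets the affected-side deficit to 0 **and**
  equalizes the side means at 0.40. Equal means matter: with the default
  asymmetric means (0.41/0.39) and 67% right-affected, the
  affected-vs-unaffected difference inherits a real +0.007 side-asymmetry
  component, so the default configuration is not a null. Grids are 1 mm
  here — exchangeability under the null does not require fine
  voxelization — which keeps the 30 000-mask study under half a minute.
  Expected rejection rate 0.05 ± 0.02.
* **Parameter recovery** — 50 cohorts of 60 patients with deficit 0.02,
  between-subject SD 0.01, equal side means (isolating the affected-side
  effect), default 0.5 mm grids. The pipeline's mean
  unaffected-minus-affected flatness difference recovers 0.02 within
  0.008 and detects it at p < 0.05 in ≥ 90% of seeds.

These problem sizes (cohort counts, n per cohort, grid spacings) are the
package's chosen design for the two studies and are fixed in code.

## Limitations

* Phantoms are ellipsoids: surface-area and diameter behaviour on highly
  non-convex anatomy is validated only against closed forms and mesh
  oracles, not against real MC segmentations.
* The published per-feature real-data means cannot be reproduced without
  the undeposited MRI cohort; the package reproduces the count-derived
  statistics exactly and the geometric/statistical machinery by property.
* Boundary-jitter noise is voxel-wise independent, not a spatially
  correlated segmentation-error model.
* Masks with rotated affines must be reoriented upstream.
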