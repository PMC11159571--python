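# Methods

This note records the models, conventions and numerical choices behind
`meniscoq`, and what its synthetic validation does and does not establish.

## Signal model and fitting

A multi-echo GRE magnitude signal is modelled as a mono-exponential decay,

    S(TE) = S0 · exp(−TE / T2*),

with two free parameters per voxel: the amplitude S0 (the model's estimate
of the signal at TE = 0) and the effective transverse relaxation time T2*.
No noise-floor or multi-compartment term is included: the two-parameter
magnitude fit is the standard mapping model for this tissue, and the
resulting Rician bias at low SNR is quantified by the tests rather than
corrected.

The least-squares problem is separable: for any fixed T2*, the optimal
S0 is the closed-form linear solution. `fit_monoexponential` therefore
minimizes over T2* alone (variable projection): a global search on a
128-point log-spaced grid over the T2* bounds, followed by vectorized
ternary refinement of the bracketing interval (120 iterations, shrinking
the bracket far below solver precision). This is deterministic, immune to
local minima, and fast enough to fit a full 120×120×40 volume in well
under a second. A log-linear initializer (`loglinear_init`, OLS of ln S on
TE with nonpositive samples excluded and a mid-range 10 ms fallback) is
also provided; on noise-free data it and the nonlinear fit agree exactly,
which the tests use as a cross-check, and an independent
`scipy.optimize.curve_fit` route and a dense 2000×2000 (S0, T2*) grid
search corroborate the optimum on noisy voxels.

Parameters and defaults:

- **T2\* bounds** [0.1, 100] ms. Meniscal tissue lies around 6–15 ms;
  the bounds are deliberately generous so clipping never shapes results.
- **NRMSE** = sqrt(SSR/K) / S0_fit, with K the number of echoes — the fit
  RMSE normalized by the fitted TE = 0 intensity. Reported per voxel; the
  regional summary uses its median.
- **Convergence flag**: a voxel fails (NaN sentinel, `converged = False`)
  only when no positive-amplitude solution exists (e.g. an all-zero
  voxel). Failures are counted, never raised.
- Fits are independent per voxel; no spatial regularization.
- Low-SNR voxels are not excluded before fitting; regional medians filter
  on the convergence flag only.

## Regional partition

The meniscus is divided by angle relative to the line connecting the
anterior and posterior horn landmarks: anterior horn [0°, 45°), anterior
body [45°, 90°), posterior body [90°, 135°), posterior horn [135°, 180°].
Conventions, where the rule itself leaves freedom:

- **Vertex** — the midpoint of the horn-to-horn segment (the symmetric
  reading; it makes 0–180° span the arc). A `centroid` vertex is exposed
  for sensitivity checks; the sweep side is always determined from the
  horn line itself.
- **Plane** — angles are computed in the axial plane (the supero-inferior
  world axis projected out); all slices of a voxel column inherit the same
  angle, giving a 3-D regional segmentation.
- **Sweep side** — the side of the horn line containing the mask centroid;
  a centroid lying on the line is an error, not a guess.
- **Ties** — bins are half-open with 180° closed, so a voxel exactly on a
  boundary goes to the more posterior region; voxels projecting behind the
  horn line are clamped to the nearest terminal bin. Exact-tie voxels are
  the one place where otherwise-exact symmetries (horn swap, grid
  rotation) can move single voxels between adjacent bins; the tests assert
  exactness away from ties.

Volumes are pixel counts (and counts × voxel volume in mm³); regional
medians use the even-count convention (mean of the two central order
statistics).

## Extrusion

Extrusion is measured on one coronal slice (an explicit input — choosing
the slice that best shows the tibial eminence is a human judgement the
package does not automate) as the maximum offset of masked voxel centres
beyond the tibial-plateau margin landmark along the medial direction. The
signed distance is reported (negative when the meniscus is contained), and
the clinical flag applies the ≥ 2 mm threshold with 2.0 included.

## Phantom

The phantom is an idealized geometry, stated as such — not anatomy. Each
meniscus is a half-annulus (C-shape) in the axial plane: inner radius
7 mm, outer radius 11.88 mm (27 in-plane voxels), uniform 8 mm thickness
(an optional wedge taper exists, off by default), arc span 180° with horns
at the ends, on a 120×120×40 grid of 0.44 × 0.44 × 1.0 mm voxels with
seven echoes at 3.1, 6.1, 9.2, 12.2, 15.3, 18.4, 21.4 ms — the acquisition
geometry of the mapping protocol this pipeline targets. Root gaps trim
1.0 mm of arc at the anterior end and 0.44 mm (one in-plane pixel) at the
posterior end, emulating the segmentation rule for torn posterior roots.
Default regional T2* values are the published group means of the regional
medians (patient or control presets); S0 is 100 with background at 5% of
that (T2* 25 ms), a fixture constant that keeps masks separable, not a
tissue claim.

Geometric alignment choices: the outer radius is a whole number of
in-plane voxels and voxelization is surface-inclusive (a voxel belongs to
the annulus if the annulus passes through it, i.e. the analytic boundary
dilated by half a voxel radially and axially). Together these make the
peripheral rim land on the voxel lattice, so a prescribed medial
displacement crosses the 2 mm extrusion threshold at exactly 2.0 mm in a
0.5 mm sweep despite the 0.44 mm grid. Meniscus centres sit 0.1 mm off
the in-plane lattice so that no voxel falls exactly on a 45° bin-boundary
ray (exact ties would otherwise make the partition's tie rule visible as
a few-percent AH/PH asymmetry).

Noise is Rician: each echo sample is the magnitude of the noiseless
signal plus complex Gaussian noise — the standard model for magnitude
MRI (the default σ = 2 gives S0/σ = 50). All randomness flows from a
single integer seed through `numpy.random.default_rng`.

What the phantom does **not** emulate: k-space acquisition, coil
sensitivities, B0/B1 inhomogeneity, susceptibility effects at tissue
interfaces, partial-volume mixing with cartilage and synovial fluid, or
realistic meniscal shape variation. Passing recovery tests therefore
demonstrates correctness of the estimation and measurement chain under
the stated signal model, not robustness to those acquisition physics.

## Statistics

- **Group contrast** (`compare_groups`): response ~ group + age + sex +
  BMI with a subject-level random intercept, estimated by REML
  (statsmodels MixedLM). When the filtered table has one row per subject
  the random intercept is not identifiable and the model collapses to the
  equivalent OLS fit, whose exact t inference is used; with pooled regions
  the mixed model is fit as stated. The random-effects structure is a
  random intercept only — region-level slopes are deliberately not
  modelled.
- **Pairwise adjustment**: Bonferroni multiplication with a cap at 1
  (m = 6 for four regions) — the meaning of the "Dunn-Bonferroni" label in
  common statistical packages.
- **Pearson correlation**: direct product-moment formula; 95% CI by
  Fisher z with half-width 1.96/√(n−3); p from the exact t transform on
  n−2 degrees of freedom.
- **Reproducibility**: ICC(A,1), the single-measure two-way
  absolute-agreement coefficient, computed from the two-way ANOVA
  decomposition, with the McGraw–Wong F-based 95% CI (Satterthwaite
  degrees of freedom). Absolute agreement is the correct form for
  scan–rescan data because a constant offset between scans is a real
  disagreement; the tests assert exactly this (offset to one scan lowers
  the ICC, offset to both does not). Bland–Altman limits are d ± 1.96·SD
  of the differences (rescan − scan), and a one-sample t-test evaluates
  zero mean difference; for degenerate identical inputs the t statistic
  is undefined and p is reported as 1.
- **Cohort simulators**: single-region cohorts draw per-subject regional
  medians from normal distributions at the study sample sizes (20
  patients vs 10 controls); the four-region variant shares a latent
  subject effect contributing half of each region's variance so that
  pooled fits exercise the random intercept. Covariates: age 53 ± 8
  (patients) / 53 ± 12 (controls), 80% female, BMI mean 28.1 / 25.5 with
  SD 4.0 kg/m² (the SD is not published; 4.0 is a typical adult
  dispersion, fixed once).

## Problem sizes and determinism

Desk-scale defaults are used throughout: one phantom fit covers ~14k
tissue voxels of a 120×120×40×7 volume (sub-second); calibration studies
use 100 replicate cohorts for power-type checks and 500 for type-I-error
calibration, which keeps the whole suite around ten seconds while leaving
Monte-Carlo margins wide relative to the asserted bounds. Every stochastic
path is seeded; reruns with the same configuration are bit-identical.

## Known limitations

- The mono-exponential magnitude fit inherits Rician bias at low SNR;
  at S0/σ = 50 the per-voxel scatter has a median around 3% while
  regional medians stay within 2% of truth. Noise-floor-aware fitting is
  out of scope.
- The angular partition's tie conventions are visible only on exactly
  symmetric synthetic grids; real segmentations have no exact ties.
- Published patient-vs-control tables from real knees cannot be
  reproduced here (no deposited data); the statistics are validated on
  synthetic cohorts and against independent oracle implementations
  instead.
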