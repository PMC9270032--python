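# Methods

## Overview

`cnscensus` implements a quantitation-and-analysis pipeline for
nucleus-labelled 3D microscopy of the larval *Drosophila* CNS: image →
nucleus centroids → point cloud → (a) census statistics and (b) a
topological classification experiment asking whether the spatial
organisation of nuclei differs between the sexes beyond counts.  All
stages are exercised end-to-end on synthetic data generated in-package.

## Segmentation model

Nuclei are modelled as bright, approximately spherical blobs of nominal
diameter 4.5 µm on anisotropic voxels.  The stages and their defaults:

* **Curvature flow denoising** (SimpleITK level-set formulation), 5
  iterations, timestep 0.125.  The PDE runs on the voxel grid; explicit
  curvature flow is stable only below ~h²/(2·dim), so larger requested
  timesteps are split into more, smaller steps of the same total
  diffusion time.
* **Blob detection**: negated Laplacian-of-Gaussian response at the
  physical scale σ = d/(2√3) — the scale at which a ball of diameter d
  maximises the 3D LoG response — with per-axis voxel sigmas σ/spacing,
  so the 4.5 µm scale means the same thing on 0.317/0.317/1.0 µm voxels.
  Local maxima within a half-diameter neighbourhood count as detections
  when they exceed `detection_threshold` (default 4) robust background
  SDs (1.4826·MAD) of the response; for noiseless input the MAD is zero
  and an epsilon above the flat background is used instead.  Expressing
  the threshold in robust SDs makes detection equivariant to global
  intensity scaling.
* **Growth and measurement**: marker-based watershed (26-connectivity)
  on the inverted intensity over a loose foreground mask, then a
  per-object half-maximum cut.  For a Gaussian blob whose FWHM equals
  the nominal diameter, the half-maximum isosurface is exactly the
  nominal sphere, so measured volumes approximate the physical object
  volume (a 4.5 µm nucleus ≈ 47.7 µm³; a 3 µm one ≈ 14.1 µm³, which the
  15 µm³ filter removes).  Centroids are intensity-weighted, reported in
  µm world coordinates (x, y, z) with voxel index scaled by spacing.

The vendor algorithm used in the original quantitation is proprietary;
equivalence on real data is not claimed.  On phantoms with separation
≥ 1.5 diameters and noise up to 10% of peak, the detector recovers the
planted count exactly and centroids to ≲ 0.05 µm RMSE.

## Census arithmetic

Counts are summarised per line as mean, CV% (sample SD over mean), and
n.  Pooled means weight each line by its animal count.  Two percent
conventions are exposed as distinct functions because both occur in the
published arithmetic and are easy to confuse: line-vs-line comparisons
divide by the comparison line; sex differences divide by the male mean.
The printed pooled means (female 10,312, n=16; male 9,396, n=15) were
derived from raw per-animal counts; the weighted mean of the printed
male line means is 9,395.33, a sub-count discrepancy caused by rounding
of the line means.  The printed pooled values are therefore carried as
explicit inputs wherever they serve as reference denominators.
Inference uses classical one-way ANOVA with Tukey HSD (statsmodels) and
the equal-variance two-sided t-test; reproducing the published p-values
would require the raw per-animal counts, which only the summary
statistics of are printed.

## Alpha persistence

The degree-1 persistence diagram of the alpha filtration is computed
in-package: scipy Delaunay triangulation; squared-circumradius
filtration values with the standard Gabriel-propagation rule (a simplex
enters at its own circumsphere if that sphere is empty of neighbouring
vertices, otherwise when its first coface enters); then Z/2
boundary-matrix reduction of the triangle columns with columns stored
as integer bitsets.  The lowest-one pairing of the triangle block alone
yields the degree-1 pairs (any reduced column is a cycle, whose lowest
edge is necessarily cycle-creating).  A union-find count of
cycle-creating edges cross-checks that every loop was paired — a 3D
alpha filtration at full scale is contractible-to-convex, so no
essential degree-1 classes can survive.

Numerical choices: diagram values are squared radii in µm²; pairs with
persistence below 1e-12 (simplices entering simultaneously) are
dropped; inputs of affine rank 2 — including clouds jittered out of a
plane by less than 1e-5 of their extent — are projected onto their
best-fit plane and handled as 2D alpha complexes, which makes analytic
test cases (triangle, circle) exact; rank ≤ 1 raises a degenerate-input
error.  The test suite validates the implementation against an
independent brute-force oracle that derives each simplex's filtration
value by constrained minimisation over the Voronoi-restricted
equidistant set and reduces the full dense boundary matrix.

## Heat kernel and Gram assembly

The persistence scale-space kernel is evaluated in closed form (sum of
Gaussian interactions minus mirrored-mass interactions, scaled by
1/(8πσ)).  Gram matrices are assembled blockwise from the stacked
diagram points with matmul-based squared distances, exploiting symmetry
(only column suffixes are evaluated), and symmetrised as (K + Kᵀ)/2.
Two performance knobs exist for large experiments and change nothing
else: `max_points` truncates each diagram to its strongest pairs before
assembly (the kernel of the pruned diagrams is then exact; pruning at
64 points keeps every prominent loop of the synthetic cohorts while
bounding the quadratic point-pair cost), and `dtype=float32` halves the
working precision of the block evaluation.  The validity tests
(symmetry, positive semidefiniteness, agreement with the pairwise
closed form to 1e-12) run in float64 without truncation.

The RBF convention for the scalar-feature baseline is
exp(−d²/(2·bandwidth²)); an alternative exp(−d²/bandwidth) convention is
available because "bandwidth" is ambiguous across SVM literatures.

## Classification experiment

Items are per-subsample summaries; all subsamples of an animal share
its group id.  Splits draw a fixed number of training animals per class
(default 6), leaving the rest as test — the summaries of one animal are
never divided between train and test, which would leak information
through shared parent clouds.  Per split, an SVM (precomputed kernel,
c=10) is trained on true sexes and, independently, on fair-coin sexes
assigned at animal level and redrawn every split; both are scored by
Pearson correlation between predicted ±1 labels and the target labels
on test items.  Constant predictions (possible under the null and when
a coin assigns one class to all training animals) yield a flagged
correlation of 0 rather than an error, so long control runs cannot
crash.  The overlap fraction — splits where the control beats the truth
— is the significance summary.  All randomness derives from a master
seed via counter-based SeedSequence keys, so experiments are
reproducible and parallelizable.

## Synthetic data

**Phantoms** render nuclei as isotropic Gaussians with FWHM equal to
the nominal diameter at rejection-sampled centres (minimum pairwise
separation, 1000 attempts per nucleus before a placement error), plus
constant background and optional Gaussian noise.  They emulate the
punctate nuclear reporter signal, not optics: no PSF anisotropy, no
bead fiducials, no intensity heterogeneity between nuclei.  Passing
count-recovery tests on phantoms therefore demonstrates correct scale
handling and thresholding logic, not performance on real tissue.

**Cohorts** are two classes of equal-size point clouds: uniform points
in an ellipsoid envelope plus jittered circles ("loops") at random
positions and orientations — loops because degree-1 persistence is
precisely a loop detector, and the classes differ only in loop count.
Three design details keep the classes matched in first-order statistics
(so that only multiscale structure distinguishes them):

* loop centres are drawn from an envelope shrunk just enough that the
  structured points' per-axis positional variance (centre variance +
  ring offset R²/3 + jitter²) equals the background's a²/5;
* every cloud has exactly `points_per_cloud` points, loops displacing
  background;
* each animal carries a lognormal overall size factor (SD 3% by
  default), mimicking organ-size variation; it dominates between-animal
  variation of distance features and is shared by both classes.

The loop surrogate is a stand-in: nothing is claimed about which
geometric feature drives sex differences in real nuclei clouds.  One
residual coupling is intrinsic to the fixed-total design: loop points
displace background points, so the loop-rich class has slightly fewer
background noise cycles.  The discriminating diagram signature of the
planted loops is joint — low birth (rings are locally dense) with
persistence above (R/2)² — not an unconditional persistence threshold.

## Desk-scale study conditions

The full-scale experiment (31 animals × 100 subsamples of 8000 points,
5000 splits) is replaced by a scaled analogue chosen once
(`scaled_study_conditions`): 8+8 animals, 1000-point clouds, loops 5 vs
25, subsample 800 of 1000 (the study's 8000-of-~10000 ratio), 50
repeats, 200 splits, 6+6 training animals, c=10, σ=1/100.  The envelope
(semiaxes 20 × 15 × 12 µm, mean spacing ≈ 2.5 µm; rings of radius
1.5 µm with 12 points) is set so alpha-diagram values are of order
1 µm², commensurate with the fixed kernel bandwidth — σ=1/100 puts the
kernel's resolution at √(8σ) ≈ 0.28 in diagram units, and a kernel
whose width is far below the diagram value scale degenerates to a
delta.  For the same reason the baseline RBF bandwidth of 1e5, tuned in
the original study on its own feature scale, is replaced in the scaled
experiment by the median heuristic (median pairwise feature distance);
with 1e5 on µm-scale features the baseline kernel is constant to
~1e-10 and every prediction degenerates.

The null-cohort calibration (equal loop counts) is reported as the mean
overlap fraction over twelve fully independent null replicates, each
with a fresh cohort and fresh split/control randomness.  A single
16-animal experiment carries chance alignment between its fixed true
labels and whatever structure the kernel happens to have — the per-
replicate overlap SD measured across draws is ≈ 0.19, and it shrinks
only as 1/√(animals), far beyond a desk-scale run — so the
replicate-averaged overlap (standard error ≈ 0.055) is the calibrated
chance-level quantity.  Null replicates use 15 subsamples per animal:
subsamples of one parent are near-duplicates, so the animal-level
statistics that drive the overlap are unchanged while the cost drops.

## Known limitations

* The blob detector is a reimplementation of an unspecified proprietary
  algorithm; counts on real data may differ.
* Heat-kernel Gram matrices at full study scale (3100 diagrams of
  8000-point clouds) are beyond a desk-scale run; the scaled study
  preserves the structure, not the magnitudes, of the original
  experiment, and the original's headline overlap value is expected to
  be configuration-sensitive.
* Whether the original analysis fed squared or square-rooted filtration
  values to the kernel is unknown; squared is the default and a
  radius-units conversion is provided for sensitivity analysis.
* The synthetic cohort's classes differ slightly in background density
  (fixed total points); diagrams carry that density shift in addition
  to the planted loops.
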