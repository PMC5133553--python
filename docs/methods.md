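# Methods

## Kinematics

The package analyses one displacement field per (subject, interval). The
convention is pull-from-reference: u(X) is stored on the grid of the
undeformed (earlier) configuration and maps it forward, x = X + u(X), with X
and u in physical millimetres. NIfTI has no standard for displacement
units, so readers take an explicit `units` flag (`mm` or `voxel`; voxel
offsets are converted through the affine's linear part at load time).

The deformation gradient F = I + ∂u/∂X is computed by central differences
on voxel indices mapped through the inverse of the affine's linear part, so
anisotropic spacings and oblique grids are handled uniformly and derivatives
are always per-mm. Central differences are second-order accurate and exact
for affine fields; the output mask is the input mask eroded by one voxel
(the stencil must lie inside the mask). A first-order `forward` scheme is
available when a one-voxel erosion is unaffordable. Directional labels
assume an RAS-oriented affine: x = left–right, y = posterior–anterior,
z = inferior–superior.

From F the per-voxel quantities follow the standard finite-strain relations:
JD = det F; E = ½(FᵀF − I); principal stretches λᵢ = √(1 + 2eᵢ) with eᵢ the
eigenvalues of E (voxels with eᵢ ≤ −½, i.e. a line element annihilated or
inverted, are masked and counted); ADG is the fractional-anisotropy form
√(3/2)·‖λ − λ̄‖₂/‖λ‖₂ applied to the three principal stretches, with the
√(3/2) constant recorded in output metadata so the map's normalisation is
unambiguous (an alternative convention applies the same form to the strain
eigenvalues; the stretch form is used here because the stretches are the
growth-rate quantities); shear angles use sin θᵢⱼ = 2Eᵢⱼ/(λᵢλⱼ) with the
axis-aligned stretches λᵢ = √(1 + 2Eᵢᵢ), the classical relation for the
angle change between initially perpendicular line elements, with
out-of-range arguments (non-physical states) masked and counted. Folding
voxels (JD ≤ 0) stay in the maps but are counted in QC and excluded from
statistics by masking. Deliberately out of scope: polar decomposition,
Eulerian/Almansi strain, and stress (which would need tissue constitutive
properties).

## Temporal normalisation, warping, smoothing

Scan intervals differ across subjects, so per-interval parameters are
normalised to a common 90-day scale. Strain components and angles (null 0)
are multiplied by 90/days. For JD the default scales the deviation from
unity, JD_adj = 1 + (JD − 1)·90/days: scaling JD itself would move the
one-sample null away from JD = 1, breaking the test it feeds; direct
scaling remains available (`jd_mode="direct"`) for sensitivity analyses.
The linearised per-day rate is itself an approximation for large
deformations (compounding is ignored), consistent with treating the
interval parameters as rates. Adjustment is guarded against double
application via map metadata.

Warping into a common (atlas) space resamples maps through a supplied
displacement field that maps each target voxel's physical position to the
source sampling position (linear interpolation for scalar/tensor values,
nearest for labels); voxels whose interpolation footprint leaves the source
mask or field of view are dropped from the output mask. Tensor maps are
resampled componentwise without local reorientation — a deliberate
simplification adequate for componentwise scalar statistics but not for
principal-direction analyses in strongly rotated regions.

Smoothing is a single explicit Perona–Malik diffusion pass on the
6-neighbour graph: v ← v + (1/6)·Σ g(d)·d over neighbour differences d,
with conductance g(d) = exp(−(d/κ)²). Differences well below the edge
threshold κ diffuse; differences well above are preserved. κ defaults to
0.1 in the map's units (of order the strain magnitudes of interest; the
largest value that still treats typical between-region contrasts as edges),
the step 1/6 is the stability limit of the stencil, and fluxes across the
mask boundary are zero, so the mask mean is conserved exactly and constant
maps are fixed points.

## Statistics

**One-sample t-tests.** Per voxel across subjects against the no-growth null
(JD = 1, strain/angle = 0), two-sided (sidedness is a deliberate
conservative choice), df = n − 1. Zero-variance voxels get p = 1 at the
null and p = 0 with a QC flag otherwise, avoiding infinite t.

**FDR.** Benjamini–Hochberg step-up, applied within each parameter map
separately (not pooled across parameters or intervals); adjusted p-values
are the monotone running minimum of m·p(i)/i. The implementation is
validated against a brute-force threshold search on all short inputs and
against an independent reference implementation.

**Random-intercept mixed model.** y_ij = β₀ + β₁·age_ij + b_i + ε_ij with
b_i ~ N(0, σ²_b) per subject and ε ~ N(0, σ²_e); age is the interval's
midpoint age in days, the only covariate, and only the intercept is random
(no random slopes). Fitting profiles the REML criterion down to the
variance ratio ρ = σ²_b/σ²_e: for fixed ρ the per-subject compound-symmetric
covariance inverts in closed form (Sherman–Morrison), giving GLS fixed
effects and the residual variance analytically, and a bounded 1-D search
(tolerance 1e-10 on ρ, with an explicit ρ = 0 boundary comparison) does the
rest. Everything X-side is precomputed once per design, so the voxel-wise
loop needs only per-voxel response sums (≈1.5 ms per voxel fit). Wald tests
use a Student-t reference with containment degrees of freedom — slope:
n_obs − n_subjects − 1 (exact for balanced designs, where the GLS slope
coincides with the within-subject estimator); intercept: n_subjects − 1.
Against a normal reference this removes far-tail anti-conservatism that
otherwise inflates the voxel-wise FDR chain; calibration was verified by
simulation against the exact within-subject t-test. Estimates match a
general-purpose REML implementation to ~1e-6 relative on β and variance
components.

**ROI classification.** ROI means are arithmetic means over masked labelled
voxels; thresholds are the 25th/75th percentiles of the parameter over all
masked brain voxels (not over ROI means), with linear interpolation between
order statistics (recorded in output metadata); classification uses strict
inequalities with a 1e-12 relative round-off guard so uniform maps classify
nothing. Empty ROIs are excluded with a warning.

## Synthetic data

The generator provides the two ingredients real longitudinal MRI would:

*Analytic deformations* (affine, rigid rotation, simple shear, uniform
scale, Gaussian radial expansion) expose closed-form u, F, JD and E at any
point. The Gaussian expansion u = α·exp(−r²/2σ²)·(X−c) has eigen-stretches
1 + αg (tangential, twice) and 1 + αg(1 − r²/σ²) (radial), so fold-freedom
is checked in closed form at construction (−1 < α < e^{3/2}/2). The default
test amplitude α = 0.3 gives peak stretches ≈ 1.3 and strains up to ≈ 0.25,
the magnitude regime of first-year brain growth.

*Simulated cohorts* follow the mixed-model data-generating process
y_ij(v) = β₀ + β₁·age_ij·blob(v) + b_i + ε_ij(v), with the subject
intercept shared across all of a subject's voxels and intervals, i.i.d.
Gaussian voxel noise, and the age effect confined to a known region.
Defaults mirror a 33-subject first-year study scanned at 2 weeks and 3, 6,
9, 12 months: midpoint ages (45, 145, 234, 325) days, inter-scan intervals
(77, 91, 92, 91) days, β₁ = −0.002 per day, σ_b = 0.05, σ_e = 0.02. All
generators are pure functions of their parameters and seed.

What the synthetic data does *not* emulate: registration error and its
spatial correlation, tissue-dependent noise, intensity artefacts,
segmentation bias, or anatomically realistic parcellations (the phantom
atlas is an ellipsoid split into equal-count slabs). Passing tests
therefore establish the correctness and calibration of the computations and
inference chain, not the biological conclusions one would draw from real
infant data.

## Pipeline

`run_pipeline` executes maps → stats → report from a YAML config. The maps
stage chains strain computation, 90-day adjustment, optional warp, and one
smoothing pass per cohort row; the stats stage runs per-interval t-tests
with FDR, per-parameter voxel-wise mixed models, and ROI classification for
JD and the six strain components. Stages are resumable: each writes a
manifest keyed by a hash of the config and input file contents, and is
skipped when the key matches and its outputs exist, so deleting a
late-stage output regenerates only that stage onwards with identical
results. Runs are deterministic given the config; `n_workers` is a
declarative option and results are independent of it by construction (the
current executor processes voxel chunks serially).

## Problem sizes and verification

Tests run on 8³–16³ grids (convergence studies 32³ → 64³, where the
max-error ratio for the Gaussian field is ≈ 3.9, confirming second order);
statistical calibration uses the full 33 × 4 cohort design — 200-replicate
slope recovery (bias within Monte-Carlo error, CI coverage ≈ 0.95), a
10,000-voxel null for t-test type-I error, and 20-replicate global-null FDR
checks on ~300-voxel masks. The acceptance script re-derives all of these
from a single seed. One caveat made explicit: under a global null with
independent voxels, the probability that BH makes *no* rejection is exactly
1 − q, so "empty significant set" checks sit on that boundary by
construction; the checks therefore run on maps that have passed the
pipeline's smoothing step, whose positive spatial dependence makes BH
strictly conservative, matching how the statistics are actually applied.

## Known limitations

- No registration: displacement fields are inputs, and their errors
  propagate unmodelled into all downstream parameters.
- Componentwise tensor warping (no reorientation) biases off-diagonal
  strain components in strongly rotating regions.
- The mixed model supports exactly one fixed covariate (age) and a random
  intercept; no random slopes, additional covariates, or spatial
  regularisation of the voxel-wise fits.
- The 90-day adjustment linearises growth within an interval.
- Containment df are exact only for balanced designs; strongly unbalanced
  cohorts would warrant Satterthwaite-type corrections.
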