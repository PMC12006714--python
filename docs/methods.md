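# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `femquad`. All lengths are millimetres; no unit
auto-detection is performed anywhere.

## Geometric model

A case is a triangulated proximal-femur surface with four labeled vertex
sets: the femoral-head patch, the lesser-trochanter (LT) patch, a shaft
patch (the 5 cm cylindrical band distal to the LT's lower edge), and the
medial fracture-line polyline. The pipeline assumes these labels are given
(segmentation and virtual fracture reduction are upstream, out of scope).

### Sphere fitting

Head and LT patches are fitted by the classical two-stage scheme: the
algebraic linear least-squares solution (expanding |p − c|² = r² into a
linear system in (c, r² − |c|²)) seeds a Gauss–Newton iteration on the
orthogonal-distance objective Σ(|pᵢ − c| − r)². Convergence is declared
when the center moves less than `tolerance_mm` (default 0.01 mm) between
iterations; non-convergence raises an error carrying the last iterate. The
0.01 mm default reproduces the tolerance setting used by commercial
fitting tools in this workflow; since those tools do not publish the
parameter's meaning, interpreting it as the parameter-change threshold is a
documented package choice, visible and adjustable in `FitConfig`.

Patch extent is summarized as `coverage_fraction`: the fraction of a
2048-point quasi-uniform direction grid within an angular reach of some
observed point direction (reach = 2× the patch's median nearest-neighbor
angular spacing, clamped to [5°, 20°] so coarse meshes are not penalized
for discreteness and sparse clouds cannot claim coverage they lack).
Coverage below 0.80 — the extent recommended when marking patches
manually — emits a warning but never fails: a half-covered sphere still
fits well on clean data, and true anatomical coverage is unknowable from
the patch alone.

### Cylinder fitting

The shaft band is fitted as a circular cylinder: axis seeded from the
dominant principal direction (SVD), in-plane center and radius from an
algebraic circle fit of the projected points, then Levenberg–Marquardt over
(axis point, axis direction as spherical angles, radius) on the residual
dist(pᵢ, axis) − r. The axis point's gauge freedom along the axis is
harmless to the optimizer and removed afterwards by re-anchoring at the
mean projection. Degenerate clouds are rejected: < 6 points, span < 10 mm
along the dominant direction, near-spherical clouds (a sphere fits the
residuals 4× better), and near-planar clouds (fitted radius ≫ data
extent). `c1`/`c2` are the extreme points projected onto the axis; which
endpoint is proximal is decided by the frame builder, which knows the head
center.

### Frame construction and signed coordinates

The coronal plane P_c contains O, C₁, C₂; the transverse plane P_a
contains O₁. "Perpendicular to P_c through O₁" admits a pencil of planes,
so P_a is pinned by taking the proximally-pointing shaft axis as its
normal — automatically perpendicular to P_c (C₁, C₂ ∈ P_c) and matching
the anatomical meaning of a transverse plane. C₂ is the endpoint nearer O,
so +Y is superior.

Anterior is identified by an explicit per-case anterior reference point
(any point clearly anterior to the coronal plane, e.g. taken from scanner
patient coordinates); the coronal normal is flipped toward it. Because the
reference is per-case, +X means anterior on *both* left and right femora —
this orientation rule *is* the mirror normalization, and mirroring a right
case into a left case (mirroring mesh, labels, and reference together)
leaves (X, Y) unchanged, which the test suite asserts. A reference within
0.1 mm of the plane is rejected as ambiguous; head–axis configurations
with triangle area ≤ 1 mm² are rejected as degenerate.

The lowest point D is the fracture-line point with minimal Y — most distal
*along the shaft axis*, not in scanner z, so the mapping is independent of
patient pose. Ties within 1e-6 mm are broken by minimal X, then
lexicographically on world coordinates (deterministic). Quadrants follow
the sign pattern with zeros assigned to the positive side (Q1 over Q2/Q4);
the boundary is a zero-measure event and any fixed convention works, this
one is documented and tested.

## Synthetic femur and cohort generator

The generator defines the study conditions for all validation; it emulates
the *output* of CT segmentation and reconstruction, not the imaging.

A parametric femur is the concatenated union of head sphere (default
radius 24 mm, center 40 mm medial / 45 mm proximal of the shaft-band top),
neck frustum, LT bump (radius 10 mm sphere, partially embedded
posteromedially), and shaft cylinder (radius 14 mm, 130 mm long) meshed at
a 2 mm target edge length. These dimensions are typical adult proximal-femur
scales. Labels are exact by construction: head patch = head sphere minus a
35° cap toward the neck (≈ 0.9 solid-angle coverage), LT patch = the bump
surface outside the shaft, shaft patch = the 5 cm band below the LT's
lower edge. The union is not watertight at component junctions; nothing
downstream requires watertightness. Optional surface noise is i.i.d.
Gaussian along each component's analytic normal; labels always come from
the noise-free geometry, so a seed fully determines the case (byte-identical
serialization, asserted in tests).

Fracture lowest points are planted analytically: a point with exact frame
coordinates (X, Y) lies on the line base + t·m̂ (m̂ = n̂_c × n̂_a, the
medial direction), every t giving the same (X, Y). Where that line
intersects the shaft cylinder the intersection is used, so D lies on the
surface; when |X| exceeds the shaft radius — which untruncated Gaussian
tails of the reference profile can produce, since the published Q-wise
spreads are summary statistics rather than anatomy — D is placed on the
same line near the axis plane instead. Rejecting or clipping such tails
would bias mean-recovery experiments; exact planting without rejection
keeps them unbiased. A short tail of polyline points at strictly larger Y
completes the fracture line.

Cohorts are simulated directly in frame space, because the published
cohort statistics are exactly frame-space distributions: per-quadrant
(X, Y) ~ N(μ_Q, diag(σ_Q²)) at the reference counts 20/21/122/42 and
moments (see `femquad.reference`). With `truncate_to_quadrant` on, draws
are rejection-sampled until the sign pattern matches the quadrant (used
for count experiments, exact); off, draws are unconstrained (used for
mean-recovery experiments, unbiased).

Grades couple to the quadrant instability rank through a Gaussian copula:
the case's rank fixes an interval of the latent normal (via the rank's
cumulative probabilities); a grade latent with correlation ρ_latent is
drawn and discretized at equal-probability thresholds (grade marginals are
unpublished; any strictly monotone encoding leaves Spearman unchanged).
ρ_latent is calibrated so the *population* Spearman of the discretized
pair equals the target (0.32 AO, 0.38 Evans, 0.40 Tang): the joint cell
probabilities of the two thresholded normals are computed from
bivariate-normal rectangle probabilities, the population mid-rank
correlation from that pmf, and the monotone map inverted by Brent's
method. This calibration is exact and seed-free — a deliberate improvement
over a simulated lookup table. Per-case randomness derives from the cohort
seed via `numpy.random.SeedSequence` spawning.

What the generator does *not* emulate: real anatomical shape variation
(no statistical shape model), fracture mechanics or propagation, CT
imaging/segmentation noise (only surface-normal jitter), and the unknown
true joint law of grades and quadrants (only its marginal structure and
rank correlation). Passing tests therefore demonstrate correctness of the
geometry and statistics pipeline under known ground truth — not clinical
validity on real CT data.

## Statistics

Spearman ρ is the Pearson correlation of mid-ranks (average ranks for
ties — both variables here are coarse ordinals, so tie handling is
essential); p-values use the t-approximation with n − 2 df (an exact
permutation option with a fixed seed exists for small n, where the
approximation is crude); confidence intervals use the Fisher z transform
tanh(atanh ρ ± z₁₋α/₂/√(n−3)). Quadrant summaries use the n − 1
denominator SD; quadrants with n = 0 are reported with NaN moments, n = 1
with NaN SDs, and flagged. Shapiro–Wilk is restricted to 3 ≤ n ≤ 5000 and
raises on constant input (where scipy's W = 1 would misleadingly read as
"normal").

## Problem sizes and numerical conventions

Validation experiments use cohorts of 205 meshed cases (the reference
cohort size) at the default 2 mm mesh resolution — a few seconds per
hundred cases — and 200 coordinate-only replicates for correlation
recovery; geometric property checks use 1000 random femur configurations
in random rigid poses. Noiseless planted coordinates are recovered to
better than 1e-9 mm; with 0.1 mm surface noise, recovery stays within a
few hundredths of a millimetre, far inside the ±1.5 mm band asserted in
tests.

## Known limitations

- The parametric femur is deliberately idealized; coverage and residual
  behaviour on pathological or osteophytic anatomy is untested.
- Fitting is plain least squares: no outlier rejection, so mislabeled
  vertices (e.g. fracture-edge vertices in the head patch) degrade fits.
- The per-case anterior reference is required input; the pipeline cannot
  infer anterior from geometry alone.
- Real-data classification correlations depend on the unpublished joint
  distribution of grades and quadrants; synthetic recovery validates the
  machinery, not the clinical effect size.
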