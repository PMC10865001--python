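# Methods

This note documents the models and numerical choices behind `myrmomorph`:
what is computed, which parameters matter, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## Outline standardization

Silhouettes are binarized at mid-grey (128/255, foreground = darker side);
inputs are expected to be effectively binary already.  The largest connected
foreground component is kept (smaller components are treated as tracing
specks) and its boundary traced with sub-pixel marching squares at level
0.5.  Image coordinates are x-right/y-down; outlines are converted to a y-up
mathematical frame (reversing traversal so they stay counter-clockwise)
before any Fourier analysis, so that the head-left/dorsal-up convention and
the 180°-flip rule are well defined.  Pixel scale is irrelevant downstream:
normalization removes size, so images need not be any particular resolution.

Outlines are resampled to **1600** points equally spaced by arc length
(starting at the original first vertex) and smoothed with **5** iterations
of an unweighted 3-point cyclic sliding average.  The window of 3 is the
smallest symmetric choice; at 1600 points one smoothing pass contracts a
circle by less than 10⁻⁵, so smoothing suppresses pixel-level jitter without
eroding shape.  Both counts are configurable (`PipelineConfig.n_points`,
`smooth_iterations`).

## Elliptic Fourier analysis

The transform uses the exact piecewise-linear (Kuhl–Giardina) integrals of
the arc-length parametrized closed polygon; the DC terms are the arc-length
centroid.  The default harmonic count is **H = 40**: the synthetic
silhouettes are band-limited to 40 harmonics by construction and
pipeline-standardized outlines reconstruct with RMS error below 0.1% of
centroid size, far under the biological signal.  H is configurable and
recorded in all outputs.

Note that under arc-length parametrization the first harmonic of an ellipse
with semi-axes (A, B) is slightly flatter than (A, 0, 0, B); the exact
quadruple holds only for the angle parametrization.  Tests therefore check
reconstruction geometry rather than that textbook identity.

### Flip-preserving normalization

Standard first-ellipse normalization makes coefficients invariant to size,
start point and rotation — including 180° rotations, which would identify a
head-left body with its head-right flip and erase exactly the
anterior/posterior structure mimicry analysis needs.  Here the procedure is:

1. Phase-shift the start point onto the first ellipse's major axis (with a
   +90° correction if the formula lands on the minor axis).
2. Rotate by the major-axis orientation ψ reduced modulo 180° into
   (−90°, +90°].
3. Scale by the semi-major magnitude.
4. Resolve the remaining half-period start ambiguity by negating odd
   harmonics if needed so that a₁ > 0.

Step 2 is the deliberate deviation from the fully canonical convention: the
applied rotation never exceeds 90°, so a shape and its 180°-rotated copy
normalize to coefficient sets differing in the sign of the even harmonics.

**Invariance domain.**  No normalization can be simultaneously invariant to
all rotations below 90° for arbitrary shapes and sensitive to 180° flips
(chaining small rotations would force full rotational invariance).
Invariance holds exactly on the intended domain: rotations that keep the
first-ellipse major axis within (−90°, +90°] of horizontal.  Input images
are prepared body-horizontal/head-left, so real data sit comfortably inside
this domain; the property tests pre-orient their random shapes the same way.

### Asymmetry removal

With the symmetry axis horizontal and the series start point on it, mirror
symmetry about the axis is equivalent to b_n = c_n = 0 (x even, y odd in the
parameter).  Asymmetry removal zeroes those coefficients — a linear
projection, hence idempotent and commuting with averaging — and is applied
to **dorsal** shapes only: dorsal asymmetry is a pose/camera artefact in
bilaterally symmetric animals, whereas lateral profiles are genuinely
asymmetric and pass through unchanged.

### Procrustes superimposition

Outlines lack landmarks, so correspondence is by point index after rolling
each outline's start to its first-ellipse major-axis end (positive x side).
Partial Procrustes then iterates: translate to zero centroid, scale to unit
centroid size, rotate each outline onto the evolving mean shape with the
optimal angle reduced modulo 180° into (−90°, +90°] — the same flip
preservation as the normalization — until the mean changes by < 10⁻⁹ or 100
iterations.  Because coefficient normalization follows, Procrustes is
largely redundant for the final coefficients; it is kept because the stated
pipeline order performs it, and it is what makes the per-outline mean shape
meaningful.

### Averaging

Coefficients are averaged arithmetically: outlines → specimen mean,
specimen means → species mean.  Specimens are therefore weighted equally
regardless of how many outlines each contributed (the two-stage mean differs
from the pooled outline mean whenever counts are unbalanced).

## Morphospace and the accuracy index

PCA is applied to the species' flattened coefficient vectors (4H
dimensions; a₁ and c₁ are constant after normalization and carry no
variance).  The retained set is the smallest prefix of components whose
cumulative explained variance reaches the **0.95** threshold;
zero-variance directions can never enter it.

Mahalanobis distances to the ant distribution are computed **in the
retained-PC space**: this matches the stated pipeline order (PCA first,
then distances between "n-dimensional vectors") and removes constant
dimensions that would make the covariance singular.  Whether the original
analysis used the full coefficient space instead is not documented; the PC
space is the package's choice and `n_harmonics`/`variance_threshold` allow
sensitivity analysis.

The ant covariance uses divisor n − 1.  When the estimate is unreliable —
fewer than 3 ant species per retained dimension, or condition number above
10⁸ — it is shrunk toward a scaled identity with a Ledoit–Wolf intensity
(recorded in the output); this is the regime shrinkage estimators are built
for, and without it the metric is unstable when the morphospace has nearly
as many dimensions as there are ant species.  If the shrunk covariance still
has condition number above 10¹², the pipeline errors rather than report
meaningless distances.  The fully degenerate case (all ants identical, zero
covariance) falls back to the unit identity, i.e. Euclidean distance — this
keeps the noise-free synthetic limit well defined.

Accuracy is 1 − D/D_max with D_max taken over **all** species of the same
aspect (ants, mimics and non-mimics): the least ant-like species anchors 0,
the ant mean anchors 1.  Two documented consequences: the index is
*relative* — adding a species farther than the current maximum weakly raises
every other species' accuracy, removing the least ant-like weakly lowers
them — and it is invariant to affine transformations of the morphospace
whenever the shrinkage policy is not triggered.

Confidence ellipses for morphospace plots use the per-group sample mean and
covariance scaled by the χ²(2) quantile at the requested level (95% default).

## Group statistics

* **Cohen's d** uses the pooled standard deviation; the reported effect is
  insect − spider, matching the direction convention of the comparison it
  reproduces.
* **BCa bootstrap CI** (default **10 000** resamples, seed required and
  echoed): groups are resampled independently with replacement; bias
  correction z₀ comes from the fraction of bootstrap statistics below the
  point estimate (clipped away from 0/1 by half a resample), acceleration
  from the jackknife third-moment formula over the pooled observations.
  Resamples with zero pooled variance are redrawn and counted; more than 10%
  redraws is an error.  With z₀ = 0 and zero acceleration the interval
  reduces to the percentile interval.
* **Variance-ratio F-test**: f = s₁²/s₂² with df (n₁−1, n₂−1), spider
  variance in the numerator and alternative "less" (spiders vary less).  The
  one-sided 95% CI is [0, f / F⁻¹(0.05; df₁, df₂)], matching R's
  `var.test` convention (cross-checked against it in the tests).  Note that
  recomputing p and CI from a variance ratio that was rounded to two
  decimals before printing shifts both in the second decimal; the tests
  document this explicitly.

## Synthetic data: what it emulates, what it does not

Body plans are lobe-envelope profiles (ellipse-like lobes on a horizontal
axis) with Gaussian waist notches: ant = head/mesosoma/gaster with neck and
petiole constrictions (depth 0.58 dorsally, 0.54 laterally — deep enough to
be unmistakably ant-like while leaving clearance for perturbation); spider =
two stocky lobes with a shallow waist; insect mimic = three slender lobes;
non-mimic = a single elongated lobe.  Dorsal and lateral variants differ in
proportions.  A species' true mimicry m blends its plan's normalized
coefficients linearly toward the same-aspect ant plan — interpolation in the
representation the pipeline measures, so m = 1 is exactly the average ant
shape and ground truth is well defined.

Default study conditions: 4 groups × 15 species × 2 specimens × 3 outlines
× 2 aspects (the magnitude of the reference data set: on the order of a
hundred species, a few hundred individuals and outlines); group mimicry
means ant 1.0, spider 0.65, insect 0.45, non-mimic 0.05, with species-level
jitter sd 0.12 truncated to [0, 1] (real mimics range from near-perfect to
barely mimetic).  The insect mean is set below the spider mean because the
insect body plan is intrinsically closer to the ant plan; with equal m the
insect group would dominate, unlike the roughly coinciding dorsal accuracy
ranges it emulates.  Exact reproduction of published per-group accuracy
ranges is *not* a generator goal.

Hierarchical noise (species 0.03, specimen 0.015, outline 0.008 of centroid
size) is a band-limited normal displacement field (harmonics 1–8 of arc
length) along the outline normals, attenuated where the body is thin — a
petiole varies on the scale of the petiole, not of the body — and rescaled
so the pooled pointwise sd equals the nominal value.  Each perturbed outline
is lightly smoothed (2 sliding-average passes), projected back to the
40-harmonic band, and accepted only if it is a simple polygon, free of
near-folds (all turning angles < 90°), and keeps at least 1% of centroid
size of waist clearance; upper hierarchy levels demand extra clearance
(+0.75 × child noise sd) so a parent never strands its children.  Rejected
candidates are redrawn, erroring after 100 attempts.

Images are rendered at 1200 × 800 (foreground 0, background 255, 8% margin)
with deterministic output: a fixed config seed reproduces byte-identical
images and tables.

**Not emulated:** appendages and their manual removal, body straightening,
occlusion interpolation, photographic noise and segmentation error beyond
rasterization, colour, phylogenetic correlation between species, unequal
group sizes, and genuinely asymmetric lateral profiles (synthetic lateral
shapes are mirror-symmetric).  Passing tests on synthetic data therefore
validate the measurement chain and its statistics, not the biological
conclusions one would draw from real specimens.

## Problem sizes and determinism

The test-suite and acceptance runs use deliberately modest sizes chosen to
exercise every code path with stable statistics: tiny rendered datasets
(3 species per group) for pipeline plumbing, a 45-species dorsal study for
parameter recovery, 10⁴ null simulations for F-test calibration, and 1000
simulations × 2000 resamples for BCa coverage.  Every stochastic component
takes an explicit seed: the generator from its config, the bootstrap from
the fit/CLI seed; the acceptance script derives all of its seeds from the
single `--seed` argument.

## Known limitations

* The accuracy index is dataset-relative (see above); scores are not
  comparable across data sets with different least-ant-like anchors.
* With few ant species and a high-dimensional retained space the
  Mahalanobis metric depends on the shrinkage intensity; the intensity is
  recorded in every output so this can be audited.
* Harmonic count, Procrustes variant and the Mahalanobis space are
  implementation choices where the original description is silent; all are
  configurable for sensitivity analysis.
* The flip-preserving normalization assumes inputs are roughly head-left
  horizontal; wildly mis-oriented inputs fall outside its invariance domain.
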