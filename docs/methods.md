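# Methods

## Model and procedure

The package treats a specimen as a two-dimensional surface embedded in
3-space, represented by an oriented manifold triangle mesh in mm units.
The analysis has four stages.

**1. Shape operator.** Per-vertex normals are area-weighted averages of
incident face normals. For each triangle, the second fundamental form
is the least-squares 2×2 symmetric tensor mapping edge tangents to
differences of vertex normals (six equations, three unknowns, solved by
batched normal equations). Face tensors are transported into each
vertex's tangent frame by the minimal rotation aligning the face normal
with the vertex normal and averaged with barycentric area weights (one
third of each incident face's area). The 2×2 eigenproblem gives
principal curvatures ordered by magnitude, |k₁| ≤ |k₂|, so that
R₂ = 1/|k₂| is the tube radius on cylindrical surfaces; signs are
retained, with the convention that the operator is the tangential
derivative of the outward normal (spheres with outward normals have
positive curvatures). R₂ is undefined (and excluded from medians) where
|k₂| < 10⁻⁶ mm⁻¹.

**2. Artifact removal.** Vertices within 3 topological rings of any
boundary loop are discarded (truncated specimen ends), as are connected
patches of machine-flat vertices (|κ_g| < 10⁻⁶ mm⁻² and curvedness
< 10⁻³ mm⁻¹) — segmentation cut planes and caps. Genuinely cylindrical
walls sit orders of magnitude above the curvedness threshold and are
never touched. If more than half of the surface would be discarded the
specimen is rejected rather than silently truncated.

**3. Inner-scale partitioning.** The retained surface is divided into
k = round(A_T/ℓ²) partitions (clamped to ≥ 2) by k-means on vertex
coordinates with k-means++ seeding, one initialization, and up to
10000 iterations; ℓ is the median R₂. Partitioning at the tube-radius
scale, rather than the mesh scale, is what makes the partition mean
curvature a meaningful local sample: a Jensen–Shannon divergence check
(base 2, shared binning, default pass threshold 0.5 bits on the median)
verifies that within-partition Gaussian-curvature histograms resemble
the whole-surface histogram.

**4. Statistics.** K_j = A_j · κ̄_gj with κ̄_gj the *unweighted* vertex
mean over the partition and A_j the sum of barycentric vertex areas (so
Σ_j A_j reproduces the retained area exactly). ΣK = Σ_j K_j; δK and
δκ_g are the area-weighted variances of K_j and κ̄_gj; ⟨C^{1/2}⟩ is the
area-weighted mean of per-partition curvedness means. Per specimen, the
statistics are averaged over a mesh ensemble (density × smoothing
variants), the whole partitioning pass is repeated with fresh seeds,
and the replicate mean and standard deviation are reported.

The unweighted partition mean presumes near-uniform triangle areas, as
produced by segmentation remeshers. Where generated fixtures would
violate this (vertex area correlated with curvature), the generators
sample so that spacing decorrelates from geometry: tube rings are
sampled uniformly in arc length, catenoid rows uniformly in meridian
arc length, pseudosphere rows uniformly in integrated curvature.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ensemble densities × smoothings | 5 × 3 | – | averages meshing-process variance; smoothing is volume-preserving Taubin at 0/5/15 iterations to avoid shrinkage confounding size |
| partition replicates | 10 | – | quantifies k-means seed variability |
| n_ring | 3 | rings | rim artifact exclusion |
| flat-patch thresholds | 10⁻⁶ mm⁻², 10⁻³ mm⁻¹ | – | zero out only machine-flat patches |
| k | A_T/ℓ² | – | one partition per inner-scale patch; rank orderings survive a tenfold change in k |
| JSD pass threshold | 0.5 | bits | within-partition homogeneity flag |
| k-means | k-means++, ≤ 10⁴ iter | – | deterministic given a seed |

Seeds: one master seed; replicate/variant seeds are derived
deterministically from it, so the pipeline is bitwise reproducible.

## Ideal surfaces

Sphere, cylinder, torus, catenoid and pseudosphere generators carry
closed-form principal curvatures at every vertex, enabling pointwise
oracle tests and the canonical total-curvature targets 4π / 0 / −4π.
Open surfaces are generated without caps and pass through the same
rim-removal path as truncated specimens. The catenoid is truncated at
|v| ≤ 1.5c by default: this keeps the surface tube-like (flare radius
2.35× the waist) — the regime where the inner-scale partition ansatz
holds — while retaining tanh(1.5) ≈ 90% of the full −4π; the
generator accepts any truncation, and at |v| ≤ 3c the direct
(unpartitioned) total curvature reproduces −4π·tanh(3) to under 1%.
The pseudosphere is the two-horn tractricoid truncated away from the
cusp circle (t ∈ [0.15, 4.5] per horn), emitted as one mesh with two
components and four boundary loops; its meridian has a cusp at the
equator (z ∝ (ρ−r)^{3/2}), so meshing across it would concentrate
spurious curvature on a ring. An independent, exact topological oracle
— the angle-defect discrete Gauss–Bonnet sum, which equals 2πχ as a
combinatorial identity — cross-checks the shape-operator route on
every fixture.

## Synthetic cohorts

`generate_tube` emulates the target anatomy as a planar U-bend (a
half-torus arch, 45% of the centerline by default) continued by a
straight descending segment, with centerline length L = c·ℓ₀ and
c = 16.6 by default. Surface degeneration is a seeded sum of 20
random-phase plane waves on the scale-free cylinder coordinates,
band-limited within a factor 4/3 of the target wavelength, normalized
to unit peak, and applied as a radial modulation ℓ₀(1 + ε·bump). The
default wavelength is twice the tube radius — on the order of the
radius, where visible degeneration occurs — chosen so the roughness
stays resolvable at the default mesh resolution (ℓ₀/5) and the median
R₂ continues to estimate the tube radius rather than the bump
curvature. Because the pattern lives in scale-free coordinates, a
uniformly resized spec reproduces the same shape exactly: δK and ΣK are
bit-identical under 2× scaling, the package's sharpest scale-invariance
check.

`growth_sequence` is a *kinematic* surrogate for mechanical growth
simulations: radius and bump amplitude increase linearly across steps
(defaults: 50% size growth, amplitude 0.1 → 0.2). It reproduces the
observable signatures — ΣK flat at the topological value, δK strictly
increasing, δκ_g non-monotonic because its 1/ℓ⁴ size factor fights the
roughness term — without any constitutive model; amplitudes are kept
moderate because that is the regime in which total curvature remains
topology-dominated, and claims tied to this surrogate are qualitative.

`simulate_feature_cohort` draws labeled feature tables directly:
Gaussian size marginals per group (normal 12 ± 1.5 mm, successful
15 ± 2, failed 18 ± 2.5), a tight Gaussian δK baseline for normals, and
bounded power-law δK tails for the diseased groups (inverse-CDF
sampling; failed stochastically dominates successful). What it does
*not* emulate: longitudinal correlation within patients, scanner/
segmentation noise, class imbalance pathologies, or any mechanistic
coupling between δK and ℓ — classifier results on these tables
demonstrate that the machinery is correct, not that clinical accuracy
transfers.

## Classifiers

Models A/B (one threshold per adjacent group pair: pooled mean or
midpoint of means) and D (independent per-axis thresholds) report
in-sample accuracy with no split, mirroring how mean-based clinical
thresholds are used; each axis is auto-oriented so group means increase
along the class order, and the 3×3 cell grid of model D resolves
ambiguous cells by nearest group centroid in standardized coordinates
(the cell-mapping rule is the package's choice). Model C is
unregularized, unstandardized multinomial logistic regression over 1000
random unstratified 50/50 train/test splits (degenerate splits are
redrawn and counted). Model E fits two binomial logistic boundaries
(normal/successful, successful/failed) with an L1 penalty on the *size*
coefficient only, solved exactly via positive/negative-part splitting
under L-BFGS-B; at λ = 0 it coincides with unpenalized maximum
likelihood (cross-checked against scikit-learn to 10⁻⁴), and at large λ
the boundary becomes a pure-shape threshold. The default λ grid is 0
plus 19 log-spaced values in [10⁻⁴, 1].

## Numerical choices and degenerate inputs

- Face tensors with numerically rank-deficient normal equations are
  marked invalid and excluded from vertex averages; vertices with no
  valid incident face are flagged invalid.
- Eigen-ordering ties (|k₁| = |k₂|) are broken positive-first.
- Antiparallel face/vertex normal pairs (pathological meshes) fall back
  to a flip instead of an unstable Rodrigues rotation.
- δK and δκ_g are clamped at 0 against floating-point cancellation
  (they are weighted variances).
- Closed meshes with negative signed volume are re-oriented by flipping
  all faces; open meshes must arrive consistently oriented.
- Distribution fits that fail to converge, and feature-space curve fits
  on degenerate (single-cluster) data, return flagged results rather
  than raising.
- Empty k-means clusters cannot occur (the backend re-assigns them);
  k is additionally capped by the number of valid vertices.

## Problem sizes

Unit and acceptance tests run on meshes of roughly 2.5–25 k vertices
(target edge lengths of ℓ/5 to ℓ/10) with single-variant,
few-replicate pipeline configurations; these sizes are past the knee of
the convergence curves for all oracle checks (sphere principal
curvatures converge at better than first order, and halving the edge
length at these resolutions still halves the median error). The full
15-variant × 10-replicate configuration remains the default for real
specimens.

## Known limitations

- The unweighted partition mean makes ΣK and δK mildly sensitive to
  systematic vertex-density gradients; strongly graded meshes should be
  remeshed toward uniform density first.
- At large bump amplitude with wavelength comparable to the radius
  (ε ≳ 0.3, λ ≈ ℓ) the surface genuinely carries net curvature
  imbalance at the retained boundary and sharp features push the median
  R₂ below the tube radius; δK orderings remain correct (and are
  verified under a tenfold k change) but ΣK drifts from 0 beyond the
  smooth-tube band.
- Geodesic (on-surface) k-means is not implemented; ambient 3D k-means
  can in principle group across a fold, which is immaterial for
  tube-like specimens but would matter for highly convoluted surfaces.
- Comparator metric definitions (GLN/GAA/MLN/MAA, sphericity, flatness)
  follow the package's own conventions documented in the curvature
  module; compare absolute values across packages with care.
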