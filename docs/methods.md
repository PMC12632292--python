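# Methods

This note documents the models, numerical choices, and validation design
behind `fetalsp`, in the order the pipeline runs them.

## Synthetic cohort model

The generator produces the cross-sectional structure of a fetal SP
morphometry study. Each cohort draws `n_subjects` (default 68) gestational
ages uniformly on 22–32 weeks. The uniform choice is a stand-in: real
cohorts state only a mean and range, and nothing downstream depends on the
GA density beyond the group sizes it induces.

Each measure value is built multiplicatively:

```
value = scale(region, metric) · shape_a(GA) · (V/V̄(GA))^γ · (1 ± AI/200) · (1 + ε)
```

* `shape_a(GA) = 1 + b·t + c·t²` with `t = GA − 22` is the growth
  archetype assigned to the region for that metric (three archetypes per
  metric by default: early-decelerating, steady, late-accelerating, with
  coefficients placing trimester percent changes in field-realistic
  ranges — thickness ≈ 30–45 %, area ≈ 64 % and deliberately uniform,
  volume ≈ 70–95 %).
* `scale` is a fixed per-region baseline (thickness ≈ 2.3 mm, regional
  area ≈ 700 mm², regional volume ≈ 1200 mm³, depth ≈ 3 mm, spread by a
  frozen internal RNG so region order is not monotone).
* Supratentorial brain volume follows a quadratic law (≈60 mL at 22 w to
  ≈250 mL at 32 w) times `(1 + δ)`, `δ ~ N(0, 0.05)`; measures scale with
  the subject's size deviation with allometric exponents γ = 1 (volume),
  2/3 (area), 1/3 (thickness, depth).
* The hemisphere factor `(1 ± AI/200)` makes the planted asymmetry index
  exact under the AI formula (right carries `+`, left `−`).
* `ε ~ N(0, cv)` is multiplicative measurement noise; per-metric noise is
  expressed as a coefficient of variation (default 0.10) because regional
  scales differ by orders of magnitude.
* A fraction of rows (default 3 %) is replaced by gross deviates
  `value·(1 ± u)`, `u ∈ [5, 8]·max(cv, 0.05)` — at least 5 noise SD from
  the clean value, the regime RANSAC is meant to absorb.

Ground truth is stored twice: closed-form (uniform-GA integrals of the
shape polynomials) and **conditional on the realized GA draws** (sample
means of the noiseless laws). The conditional values are what a perfect
analysis of that particular sample recovers, so the noiseless-recovery
invariant holds exactly rather than up to GA-sampling error.

What the generator does **not** emulate: realistic cortical geometry,
MRI intensities, segmentation or registration error, spatial correlation
between neighboring regions, longitudinal repeats, or GA-dependent noise.
Passing tests therefore demonstrate that the statistical machinery
recovers planted effects under idealized sampling — not that it would be
unbiased under parcellation misalignment or motion artifacts.

## Surface fixtures and voxelization

The outer fixture surface is an icosphere (subdivision 4–5) radially
perturbed by a random unit-peak combination of degree-l real spherical
harmonics; the inner surface is an inward offset along outer vertex
normals by a prescribed thickness field, which preserves vertex
correspondence by construction. Region labels are angular sectors —
colatitude bands of 4/5/5/3 azimuthal sectors (17 per hemisphere),
computed from `(|x|, y, z)` so the scheme is exactly mirror-symmetric
about the sagittal plane x = 0. Vertices exactly on the plane are
assigned rightward; the resulting one-edge-wide asymmetry in sector areas
is bounded and shrinks with mesh refinement (tested).

Voxelization labels every voxel whose **center** lies between the two
surfaces. The inside test is a pseudonormal signed distance to the
nearest corresponded vertex (cKDTree); voxel centers sit at
`origin + (index + 0.5)·voxel_size` (half-voxel convention). This is
accurate to the mesh sagitta (≈0.01 mm at subdivision 5 on a 25 mm
sphere) and fast without a ray-casting backend; it assumes the dense,
smooth, star-shaped fixtures this module generates, which is why real
label volumes are accepted as *inputs* rather than produced here. The
voxel-center estimator's error oscillates with lattice alignment, so the
convergence test averages over shifted grid origins (an `origin`
parameter exists for exactly this).

## Morphometry discretizations

* **Taubin smoothing**: alternating uniform-Laplacian steps with factors
  λ = 0.5 then μ = −0.53, 10 iterations by default; one "iteration" is a
  full (λ, μ) pair. Requires `0 < λ < −μ < 1`.
* **Curvature**: cotangent Laplace–Beltrami with mixed-Voronoi vertex
  areas (Voronoi corner areas for acute corners, barycentric fallback at
  obtuse ones). Barycentric areas alone bias H by ~14 % at the twelve
  valence-5 vertices of an icosphere; the mixed areas are vertex-uniform
  to ~10⁻⁵. The QC smoothness error is the mean over vertices of
  |H(v) − mean H(neighbors)|.
* **Inflation**: explicit mean-curvature flow — displacement
  `(W v − D v)/A` with cotangent weights W and Voronoi areas A — followed
  by an area-restoring rescale about the centroid each iteration
  (default 300 iterations, step 0.9 of the per-iteration stability
  bound). Because the displacement is the discrete mean-curvature normal,
  a sphere shrinks uniformly and the rescale restores it: the sphere is a
  true fixed point (0.06 % radial deviation), and a degree-6 harmonic
  perturbation of relative amplitude 10 % is damped below 1 % of its
  input amplitude while total area is preserved to <0.1 %.
* **Depth** is the signed projection of `(original − inflated)` vertex
  offsets onto inflated-surface normals, minus its minimum over all
  vertices (so min = 0 exactly). The displacement is kept signed before
  rescaling; the rescale absorbs negativity.
* **Triangle region assignment** for per-region areas: majority vertex
  label, ties to the lowest region id — a deterministic partition, so
  per-region areas sum exactly to the total.
* **Boundary distance error**: Euclidean distance transform of the
  label-boundary mask (labeled voxels with a background neighbor),
  sampled at vertex positions by trilinear interpolation, in mm.

## Robust fitting (RANSAC + AIC)

All covariate corrections use one primitive. For each degree d ∈ {1, 2}:
200 minimal subsets (d + 1 points) are drawn from a generator seeded by
`seed` (default 42); each trial fit is scored by the **median absolute
residual** over the full sample, and the best trial defines the consensus.
An adaptive per-trial threshold was rejected because it rewards sloppy
fits whose inflated residual spread admits every point. Inliers are the
points within `3.0 × 1.4826 × MAD` of the best trial's residuals (an
absolute floor of 10⁻⁹ of the response scale makes noiseless data keep
every point, so the zero-noise fit equals ordinary least squares
exactly). The 3σ multiplier keeps ≈99.7 % of clean Gaussian points, which
is what lets a 20 % gross-outlier contamination coexist with the 75 %
minimum-inclusion rule: a 2σ threshold trims ~5 % of clean points and
collides with that floor. If the consensus still falls below 75 % of the
sample the fit falls back to full-sample least squares and is flagged.

Final coefficients come from an OLS refit on the consensus inliers, in a
basis centered at GA = 27 (median of the covariate when the covariate is
not GA) for conditioning, reported in the raw basis. AIC is computed on
the full sample from the refit model, `n·log(RSS/n) + 2k` with
`k = degree + 2`, with an RSS floor that keeps noiseless fits finite
while preserving the parameter penalty; the lower-AIC degree wins, ties
to linear.

A structural property worth knowing: under a *linear* generating law the
quadratic model's deviance improvement is asymptotically χ²₁, so AIC
selects the true degree with probability ≈ P(χ²₁ < 2) ≈ 0.84 at **any**
noise level — this is the classic AIC overfit rate, pinned by a test. For
a quadratic law, selection is essentially certain once the curvature
exceeds the noise; the degree-selection validation therefore runs on the
quadratic law at calibrated noise.

Residualization is sequential — GA first, then residual brain volume
(brain volume minus its GA trend), then, for thickness, regional depth
(itself pre-corrected for GA and residual volume) — per
region × hemisphere × metric cell. Order matters with correlated
covariates and is pinned by a regression test. Wherever group means,
percent changes, or asymmetry indices are formed, the correction is
**level-preserving** (the prediction is centered before subtraction):
pure residuals are zero-mean, which would make ratios of means
undefined; centering the prediction removes the covariate trend while
keeping each scope's mean level. Covariates whose spread is below 10⁻⁶ of
their parent measure's scale (the noiseless degenerate) are skipped.

## Group statistics

Percent change uses the delta-method SE
`se² = (100/m₁)²·(se₂² + se₁²·(m₂/m₁)²)` (validated against a
100 000-draw parametric bootstrap to <5 %), CI = pc ± 1.96·se; it is
undefined (flagged, not zeroed) when the baseline mean is ≤ 0. Homotopic
growth and AI-change comparisons are Z-tests with SEs pooled in
quadrature. Lateralization is a one-sample t-test of per-subject AIs
against zero, Cohen's d = mean/SD; the paired test is the t-test on
R − L differences. Zero-variance inputs follow a degenerate contract
(p = 0 for a nonzero mean, p = 1 otherwise, flagged). FDR families are
**regions within metric** (and within group for per-trimester tests),
using the Benjamini–Hochberg step-up.

ANCOVA fits a general linear model with effect (Sum) coding and type-III
sums of squares; partial η² = SS_effect/(SS_effect + SS_error) against
the error stratum of the effect. Repeated-measures designs use the
univariate split-plot approach: between-subject effects (GA, sex,
residual volume) are tested on subject-level aggregates against the
subject-level residual; within-subject effects (region, hemisphere, and
their interactions with the covariates) are tested in the full model with
a subject main effect, against the within-subject residual, with
interaction columns coded reduced so they are not aliased with the
subject dummies. No sphericity correction is applied; the implementation
is labeled univariate. Rank-deficient designs are rejected with an error
rather than silently dropped.

The planted-effect-size validation fixes the *realized* variance split:
noise is orthogonalized against the GA design and rescaled so the sample
variance fraction equals the planted value exactly, making the η²
recovery check sharp instead of a sampling-noise lottery.

## Trajectories and clustering

Fitted models are sampled on the fixed grid 22.0, 22.1, …, 32.0 (101
points); the relative growth rate is the forward finite difference
normalized by the **baseline** (fitted value at 22.0),
`rate_i = 100·(v_{i+1} − v_i)/(0.1·b)`, assigned to interval midpoints
22.05 … 31.95. Baseline-at-start makes the Riemann sum of the rate curve
telescope exactly to the cumulative growth `100·(v(32) − v(22))/v(22)` —
the AUC–endpoint identity — and makes rate curves invariant to rescaling
the measure, so clustering compares trajectory shapes, not sizes.

Cluster metrics: peak rate is the curve maximum (ties → earliest
midpoint); AUC is `Σ rate·0.1`; growth density is the SD of the rate
curve smoothed by a centered moving average of 0.5 weeks (5 samples,
truncated at the edges — the smoother is unspecified upstream and chosen
here). Ward linkage on Euclidean distances between rate curves; both
hemispheres enter as separate items (required for the symmetry matrix);
k is chosen by maximum mean silhouette over candidates 2–8, with an
`override_k` escape hatch standing in for dendrogram inspection, ties to
the smaller k. Identical profiles are a flagged degenerate case with
k forced to 1.

The homotopic symmetry matrix: cell (i, j) counts regions with left
hemisphere in cluster i and right in cluster j, normalized by the number
of unique regions touching cluster i or j; the diagonal is 1 exactly when
every contributing region co-clusters bilaterally.

## Validation design and problem sizes

The test suite checks each operation against an independent oracle
(analytic geometry, brute-force enumeration, closed forms, or planted
simulation truth) and the pipeline end-to-end: with all noise off, the
estimated percent changes, asymmetry indices, and cluster labels equal
the generator's ground truth exactly. Problem sizes were chosen to give
stable statistics at interactive runtimes: 20 cohort seeds of 68 subjects
for parameter recovery; 20 seeds and 20 noise levels × 5 repetitions for
cluster recovery; 200 seeds for degree selection; 1000 simulations for
the type-I error checks (t-test at n = 30, Z-test at n = 100 per group,
where the asymptotic normal approximation the Z-test relies on is valid);
100 seeds at n = 200 for effect-size calibration; subdivision-4/5
icospheres and 0.5 mm voxels for the geometry oracles.

## Known limitations

* The one-sample AI t-test is not robust: gross outlier rows surviving
  into per-subject AIs can inflate their variance and cost power; the
  robust machinery protects trend estimates, not group-mean tests.
* AIC's ≈16 % overfit rate for truly linear trends is inherent to the
  criterion; it costs nothing downstream (an overfit quadratic tracks the
  line on the fitted range) but shows up in degree-selection counts.
* The default synthetic archetypes for surface area are deliberately
  similar (uniform growth), so clustering that metric is weakly
  determined at realistic noise — by design, clustering quality is only
  asserted on fixtures with stated separation-to-noise.
* Voxelization's pseudonormal inside-test and the angular-sector labels
  are fixture machinery, not general segmentation tools.
* The repeated-measures ANCOVA is univariate without sphericity
  correction; with strongly non-spherical covariance its within-subject
  p-values are optimistic.
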