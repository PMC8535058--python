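# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pclt2`. It is written for a reader who wants to judge
what the package computes and what its synthetic validation does and
does not demonstrate.

## Signal model and T2 fitting

The decay of a multi spin-echo magnitude signal is modelled per voxel as
S(TE) = S0·exp(−TE/T2), two free parameters, no noise-floor offset. An
optional three-parameter variant with a constant offset C is available
(`FitConfig(use_offset=True)`) but off by default: with only five echoes
the extra parameter costs a residual degree of freedom and the offset is
poorly identified.

Fitting is vectorized Levenberg–Marquardt over all ROI voxels at once,
parameterized in (S0, R = 1/T2) for conditioning, seeded by a masked
log-linear regression of ln S on TE (echoes with S ≤ 0 are excluded from
the seed). Convergence is declared when a step improves the cost by less
than 10⁻¹⁰ relative, or when no damped step improves it (local minimum).
An independent per-voxel check against `scipy.optimize.curve_fit` agrees
to < 0.1 ms in the tests.

Fit quality: R² is computed on the untransformed residuals of the
nonlinear model and adjusted for degrees of freedom with p = 2 (n = 5
echoes leaves n − p − 1 = 2). A voxel is **valid** iff the fit
converged, R²_adj ≥ 0.9, and T2 lies inside (1, 2000) ms. Invalid voxels
carry NaN — never zero, which would silently bias ROI means. Degenerate
inputs (constant signal, zero total sum of squares) are invalid without
raising. A config flag can drop the first echo (a common mitigation of
stimulated-echo contamination in multi spin-echo trains); the default
uses all five echoes.

Two consequences of the R²_adj gate worth knowing: (i) at 2 % noise the
estimator is effectively unbiased at T2 ≈ 35 ms (measured bias
< 0.1 ms over 10⁴ decays) and pure-noise voxels are rejected > 99 % of
the time; (ii) the gate preferentially rejects *short*-T2 voxels (they
decay into the noise floor by the later echoes), so on data whose T2
distribution has substantial mass below ~15 ms the post-filter ROI mean
exceeds the underlying field mean. This selection effect is a property
of the method itself, visible on the noisy phantoms (post-filter entire-
ligament means run a few ms above the generator's field mean); noiseless
phantoms recover the field exactly.

## Centerline, length, subregions

The ligament centerline is computed by a two-pass slab-centroid
construction rather than voxel skeletonization, which is brittle on
strongly anisotropic voxels (0.4 × 0.4 × 3.2 mm) and masks only ~3
slices thick:

1. the principal axis of the mask's voxel-center point cloud (SVD)
   defines a provisional longitudinal direction; voxels are binned into
   ~1 mm slabs along it and per-slab centroids are smoothed with a cubic
   smoothing spline (allowed rms residual 0.3 mm per centroid);
2. voxels are re-binned by the arc length of their nearest point on the
   pass-1 curve and the centroids recomputed. This second pass makes the
   sections locally perpendicular to the tube axis, removing the
   systematic overestimation that oblique end sections otherwise cause
   on curved masks;
3. the spline is extended along its end tangents in 0.1 mm steps while
   still inside the mask, so the polyline reaches the true insertion
   ends rather than stopping half a slab short.

Length is the polyline arc length in physical mm (voxel centers at
index × spacing; slices at 3.2 mm center-to-center = 3.0 mm thickness +
0.2 mm gap). Measured accuracy on known geometry: straight tubes to
±0.5 mm, quarter-circle arcs to < 1 %, rotation invariance to < 1 %.

Each mask voxel inherits the arc-length fraction s of its nearest
centerline point: PR for s < 0.25, CR for 0.25 ≤ s < 0.75, DR for
s ≥ 0.75 — boundary ties fall to the central region, the largest, which
minimizes edge artifacts. The proximal end is identified as the end
nearer the femoral bone label (override available for label-free masks).
The partition is exact (coverage + disjointness) by construction, so the
entire-ligament mean is identically the n-weighted mean of the three
subregion means.

## Insertion boxes

On the central parasagittal slice (the slice of largest ligament
cross-section; the middle one under ties), the cortical interface is the
least-squares line through bone-boundary pixels within 10 mm of the
ligament endpoint. The 5 × 10 mm (height × width) box is centered on the
endpoint's projection onto that line, shifted half a pixel toward the
ligament (the physical interface lies between bone and non-bone pixel
centers), and offset so 25 % of its height lies bone-side. Orientation
tracks a tilted interface to within 5° in tests; the rasterized box area
is 50 mm² to within one pixel row. The analysis is 2D on that single
slice; 3D insertion footprints are out of scope.

## GLCM texture

Co-occurrence counts are accumulated per slice at a 1-pixel offset in
the four in-plane orientations (0°, 45°, 90°, 135°), summed over
orientations and slices before normalization, symmetric (each pair in
both orders). Pairs require both pixels valid and inside the ROI.
Through-plane offsets are not offered: at 8× slice anisotropy they are
not comparable with in-plane offsets.

Quantization default is integer milliseconds saturated to 0–80 ms, so
gray levels are on the T2 scale and the GLCM marginal variance is
directly comparable with the squared first-order ROI SD; on fitted noisy
phantoms the ratio sits near 0.9 (saturation of the >80 ms tail pulls it
slightly below 1). A fixed-bin alternative is available. Features are
the Haralick definitions — entropy −Σp·log₂p (base configurable; base
changes absolute entropy only), contrast Σ(i−j)²p, homogeneity
(inverse difference) Σp/(1+|i−j|), and marginal variance Σ(i−μ)²pₓ.
Because the underlying quantization and log base of published absolute
texture values are generally unknowable, only structural relationships
(variance ≈ SD², shift invariance, constant-image limits, brute-force
oracle equality) are asserted, never absolute entropy values.

## Statistics

* **Length**: two-tailed paired Student's t. Identical pairs give t = 0,
  p = 1; a nonzero constant difference is degenerate and reported as
  p → 0 with a warning rather than an exception.
* **T2 and texture metrics**: two-sided Wilcoxon signed-rank, exact for
  up to 25 nonzero differences by full enumeration of the 2ⁿ sign
  assignments (dynamic programming over the rank-sum generating
  function; mid-ranks doubled to stay integral), normal approximation
  above. Zeros are handled by the Pratt rule (ranked, then dropped from
  the statistic) — chosen because it is the conservative convention when
  the zero-handling of the original analysis is unspecified.
* **Subregions**: Friedman's test on within-specimen ranks; when the
  overall p ≤ α, Dunn's pairwise comparisons on the rank sums,
  z = |Rᵢ−Rⱼ|/√(nk(k+1)/6), reported both uncorrected and
  Bonferroni-corrected across the three pairs. The corrected value is
  the headline; both are emitted because published post-hoc conventions
  vary.
* **Sample size**: smallest per-group n whose two-sample two-tailed
  noncentral-t power reaches the target (0.8 at α = 0.05, d = 1.6 gives
  n = 8). The two-sample formulation is used because it is the
  convention of standard sample-size calculators for a Cohen's d between
  two groups; a paired formulation with d_z = 1.6 would give n ≈ 6 and
  is provided as an option, not the default.
* α = 0.01 throughout by default, configurable.

The empirical size of the signed-rank test at α = 0.01 is verified
against its binomial band over 2000 simulated null cohorts.

## Synthetic phantom cohort

The generator's defaults are the study conditions, fixed once:
acquisition grid 0.4 × 0.4 × 3.2 mm, 5 echoes at 13.8–69.0 ms; ligament
= curved tube (arc radius 45 mm, tube radius 3 mm — a gently curved
structure spanning ~3 slices) of length 37.8 mm unloaded and 44.0 mm
loaded; subregion T2 plateaus 41.1/34.7/32.7 ms unloaded and
45.7/36.5/33.4 ms loaded with 2 mm smoothed transitions; voxel-wise
truncated-normal texture field with within-ROI SDs of ~21–26 ms
(per-subregion recentring makes the ground-truth subregion means equal
the targets by construction); short-T2 (5 ms) bone blocks abutting both
tube ends across planar interfaces; S0 = 1000 with magnitude noise of
σ = 2 % S0 (Gaussian-magnitude default, Rician optional — the flag
changes only the noise draw, not geometry or ground truth). Loading is
emulated by scaling the arc length at fixed radius and substituting the
loaded T2 values — the pipeline needs paired data with the right
statistical structure, not biomechanics.

Cohorts draw one specimen-level offset per metric — length (SD 1.8 mm)
and subregion T2 means (SDs 1.7/0.7/1.5 ms) — shared between the two
configurations of a specimen, so the paired contrast is preserved while
specimens vary; child seeds spawn deterministically from the master
seed. A null mode regenerates the loaded arm with the unloaded
parameters for type-I-error checks.

What the phantom does **not** emulate: real knee anatomy, partial-volume
synovial fluid, spatially correlated tissue texture (the voxel-wise
field is independent noise, so absolute texture features of phantoms are
modelling artifacts), magic-angle orientation effects, B1/stimulated-
echo bias, and registration error between configurations. Passing tests
therefore demonstrate the correctness of the estimators and the
statistical machinery under the stated data model — not the biological
validity of any T2 threshold.

## Problem sizes and numerical choices

Noise is drawn only within a 4 mm bounding box around labeled
structures (the remote background, which no analysis stage touches,
stays zero). The multi-seed detection experiments run the study with
insertion-box and texture computation disabled — neither feeds the two
quantities under test (length, entire-ligament mean T2) — at 50 master
seeds in the test suite and 25 in the acceptance script, with n = 10
specimens each; these sizes are the package's own choice of scale for a
stable rate estimate. Histogram range 0–80 ms (1 ms bins) matches the
usual display scaling of ligament T2 maps. All randomness flows from a
single integer seed per entry point.

## Known limitations

* Mono-exponential, no Rician-bias correction: at very short T2 or very
  low SNR the estimator inherits magnitude-noise bias; the R²_adj gate
  masks, not removes, this.
* The centerline construction assumes one elongated, 26-connected mask;
  branching structures are rejected, not handled.
* The insertion-box interface fit assumes a locally straight cortical
  boundary within the 10 mm window.
* Exact Wilcoxon enumeration is conditional on the observed ranks (ties
  included); for heavily tied small samples the attainable p-values are
  coarse, which is a property of the statistic, not the implementation.
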