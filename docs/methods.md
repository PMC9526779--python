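# Methods

This note describes the models implemented in `petinsert`, the choices
made where the design was genuinely open, and what the in-silico
validation does and does not demonstrate.

## Fractional sphere masks

A sphere is rasterized by sub-voxel center counting: each voxel of the
image grid is conceptually subdivided by `factor` per axis (default 16),
and the voxel value is the fraction of the `factor^3` sub-voxel centers
whose distance to the sphere center is ≤ d/2, boundary inclusive. This is
mathematically identical to upsampling the grid by `factor`, drawing a
binary mask at fine resolution and block-averaging back — but is computed
only inside the sphere's bounding box, so no `factor^3`-sized array is
ever materialized.

Properties relied on elsewhere:

* interior voxels are exactly 1, exterior voxels exactly 0; fractional
  values occur only where the surface crosses a voxel;
* mask volume (sum × voxel volume) converges to π d³/6 as 1/factor; at
  factor 16 on the 1.042 × 1.042 × 2.8 mm grid the error is < 0.05% for
  all six sphere sizes (the acceptance tolerance is 0.5%);
* volumes shift by < 0.5% under sub-voxel translations of the center, so
  the (unknown) physical sphere centers do not matter at this factor. The
  default regeneration places centers on a voxel center, which also makes
  the mask exactly mirror-symmetric in x and y.

The boundary-inclusive (≤) membership rule is a tie-break of measure zero;
any rule that agrees almost everywhere produces identical masks except on
exact-surface sub-centers.

## System model

The scanner is modeled as a stack of independent 2-D parallel-beam
acquisitions, one per axial slice — not a 3-D time-of-flight cylindrical
geometry. The insertion method itself is model-agnostic (insertion and
reconstruction must simply share one model), and the 2-D stack preserves
every mathematical property the method relies on (linearity, adjointness,
Poisson statistics) at desk-scale runtimes. Time-of-flight is not modeled.

Expected counts per bin:

    E[s,a,r] = sensitivity · T · eff[a,r] · exp(-∫ μ dl) · L[s,a,r](G_σ * λ) · A_bin

* **Line integrals** `L` use exact pixel/strip overlap weights: radial bin
  r at angle a is a strip of width `radial_spacing`; a pixel's weight is
  its overlap area with the strip divided by the strip width (units mm).
  The projected-area profile of an a×b pixel is the convolution of two
  boxes of widths a|cos θ| and b|sin θ|, whose CDF is closed-form, so the
  weights are exact rather than sampled. Two consequences are load-bearing:
  per-angle totals are exactly conserved (each strip family tiles the
  plane), and the back projector is the exact matrix transpose, which the
  EM reconstructions assume. A Joseph-style sampled projector would also
  work but passes the conservation/adjoint tests only approximately.
* **Resolution** is an in-plane Gaussian of FWHM 4.0 mm (σ = FWHM/2.3548)
  applied to the image inside the projector and its adjoint. No kernel is
  specified by the emulated console; image-space blur is the simplest
  self-adjoint choice, and 4 mm is representative of whole-body PET
  reconstruction resolution. Reflect-mode boundaries make the discrete
  operator symmetric and exactly sum-conserving.
* **Attenuation** factors are exp(−∫μ dl) per line of response with μ in
  cm⁻¹ (water 0.096, lung insert 0.03 at 511 keV), path length converted
  mm → cm.
* **Sensitivity** (default 2×10⁻³ expected true counts per Bq·s for a unit
  source at isocenter) folds geometric and detector efficiency into one
  scalar; per-bin detector efficiency variations are an optional map
  defaulting to 1. The default puts ~1×10⁸ true counts into a ~330 s
  acquisition of the 42 mm phantom slab, the count density of a clinical
  NEMA acquisition on a modern digital PET ring; it also reproduces
  replicate-to-replicate recovery-coefficient scatter (SD ≈ 0.01–0.06) of
  the same order as physical experiments.
* **Scatter and randoms are not simulated.** Inserted data contain only
  true coincidences; any baseline keeps whatever it already contained.
  This mirrors the hybrid method's own stated limitation.
* Geometry defaults: 96 angles over [0, π), radial spacing equal to the
  smallest in-plane voxel pitch, radial bins covering the grid diagonal.

Poisson realization draws independent counts per bin from the expected
sinogram with `numpy`'s PCG64 generator; a seed fully determines the
realization.

## Insertion

The hybrid step follows the acquired-data route even in silico:

1. the baseline reconstruction is *encoded* into integer per-slice
   intensities with per-slice RescaleSlope/RescaleIntercept tags and
   *decoded* again (AC = intensity·slope + intercept), so the background
   estimate sees exactly what a DICOM consumer would see (quantization
   error ≤ slope/2 per voxel);
2. the background AC baseline is the mean over 12 spherical background
   VOIs (37 mm, two rings of six, ≥ 15 mm surface clearance from the lung
   insert and every sphere) of each VOI's fraction-weighted mean — on a
   uniform background the estimate is placement-independent, so the layout
   is convenience, not calibration;
3. the insertion map is (Σ sphere masks) × baseline × SBR, where SBR is
   the *resulting* (measured) ratio, not the nominal 2/4/6/8;
4. the map is forward-projected with the baseline's duration, Poisson
   realized, and summed with the original sinogram.

Noise placement: the default realizes Poisson noise in the *sinogram*
domain (expected projected counts → counts), which is the statistically
standard model for count data — the sum of the realized baseline and the
realized insertion is then itself Poisson with the correct mean. An
image-domain option (`noise_domain="image"`: realize per-voxel
disintegration counts before projection) is provided; it produces
sinograms whose bins are weighted sums of Poisson variables rather than
Poisson, and is off by default. The choice is recorded in the stage log.

## Reconstruction

Standard MLEM/OSEM with multiplicative updates, 0/0 → 0, zero-sensitivity
voxels pinned at zero, uniform positive initialization inside the support,
fixed iteration count (no stopping rule), Gaussian post-filter applied
once at the end. Because the operator carries the full physical scale, the
iterate is in Bq/mL directly. Subsets partition the angles interleaved
(subset s takes angles s, s+S, …) and must divide the angle count exactly;
the console-style nominal of 34 subsets is resolved against the 96-angle
default to the nearest divisor, 32, and logged. OSEM with one subset is
bit-identical to MLEM. The regularized (penalized-likelihood) algorithm of
the reference tables is not implemented — its internals are proprietary —
and its rows are consumed as data only.

## Quantification and statistics

VOIs for measurement reuse the sphere definitions (center + internal
diameter) and the fractional-mask machinery: AC_mean is the
fraction-weighted mean, AC_max the plain maximum over voxels with any VOI
coverage (max-voxel semantics, as clinical analysis software reports it).
RCs are computed per replicate, then averaged and SD-ed per
(sphere, SBR, algorithm); comparisons consume the replicate-averaged
tables (48 paired values for the shipped two-algorithm design).

The rank tests, the normality test and Bland–Altman are implemented from
their defining formulas (average ranks with tie correction, exact
Mann–Whitney enumeration up to total n = 16 and corrected normal
approximation above, Spearman p via the t approximation with n−2 df,
D'Agostino's skewness and Anscombe–Glynn kurtosis transforms with p from
χ²(2 df)) so that small-sample behavior is testable against enumeration
and direct-summation oracles; only special functions (erf, incomplete
beta) come from libraries. Agreement against `scipy.stats` at machine
precision is part of the test suite, as an independent cross-check, not
the implementation. The Bland–Altman percent convention defaults to
percent of the reference (experimental) value, with percent-of-pairwise-mean
as an alternative; the convention used is recorded in the output. The
normality p-value is withheld (NaN) below n = 20 or for degenerate
(all-equal) differences.

## The digital phantom and what the twin protocol shows

The generator emulates the body image-quality phantom: a super-ellipse
torso cross-section (half-axes 150 × 110 mm, exponent 2.5), a 50 mm
central lung insert (μ = 0.03 cm⁻¹), and six spheres (internal diameters
12.43/9.89/7.86/6.23/4.95/3.95 mm) on a 57.2 mm ring in the central slice.
None of these dimensions are prescribed by the emulated protocol's
published description; they follow common body-phantom conventions and are
plain configuration — no quantitative check depends on them. Filling
scenarios use the published activity pairs (background ≈ 5.3–5.5 kBq/mL;
resulting SBRs 2.07/3.93/6.03/7.97 and a cold-sphere 0:1 baseline), three
replicates of 323/334/346 s each. Decay over the ~6 min session is
ignored; the three stated durations are taken as already
decay-compensated. The out-of-field scatter phantom contributes nothing
because scatter is not modeled.

The production grid is 128 × 128 × 15 at 2.6 × 2.6 × 2.8 mm — coarser
in-plane than the clinical 384-matrix so that the full torso fits a
desk-scale sinogram; mask generation and the printed-volume checks use the
clinical 1.042 mm spacing, where grid extent is not a constraint.

`run_validation_protocol` validates the insertion machinery by same-model
comparison: the direct-acquisition arm and the insertion arm share the
projector, so near-perfect RC correlation (Spearman ρ > 0.95 across
24 sphere × SBR conditions), non-significant Mann–Whitney p and
small Bland–Altman means demonstrate that the mask → baseline → projection
→ noise → summation → reconstruction chain is unbiased and
statistically consistent. It deliberately cannot detect forward-model
mismatch with a physical scanner — the same blind spot the hybrid method
itself has, which is why the published physical-vs-simulated RC tables
ship as the external reference for the agreement battery.

## Numerical choices and degenerate inputs

* Strip-overlap CDFs switch to the single-box form when one box is ≤ 1e-9
  of the other, avoiding a catastrophic difference quotient at axis-aligned
  angles.
* Sub-voxel offsets are computed in voxel units (dyadic for factor 16)
  before scaling to mm, keeping center-on-voxel masks exactly symmetric.
* EM updates use `where=`-guarded divisions; an all-zero sinogram
  reconstructs to exactly zero after one iteration.
* Geometry matrices are cached per (grid, model) pair; the cache is
  cleared beyond 8 entries.
* Series encoding picks slope = slice-max / 32000 (intensity headroom of a
  signed 16-bit DICOM), intercept 0; all-zero slices get slope 1. The bit
  depth of the emulated console images is unspecified, so the quantization
  bound (≤ slope/2) is this package's own contract.
* Replicate seeds derive from one master seed via `SeedSequence`, reduced
  mod 2³¹.

## Known limitations

* 2-D slice-independent geometry: no axial cross-talk, no oblique LORs, no
  time-of-flight; absolute RC levels are therefore not comparable to any
  specific physical scanner — only the internal consistency of the
  insertion method is probed.
* Scatter and randoms absent (by design, matching the method's scope).
* Resolution is a single stationary Gaussian; no depth-dependent or
  crystal-dependent PSF.
* The penalized-likelihood reconstruction of the reference tables is not
  implemented; per-algorithm agreement involving it can only be computed
  on the shipped fixture.
* The sinogram-domain noise default means inserted and baseline noise are
  independent; correlations a physical scanner might introduce between
  neighboring bins (e.g. via randoms smoothing) are not represented.
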