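# Methods

This note documents the models, conventions, and design choices behind
`retinoconn`, and what the synthetic-study generator does and does not
emulate.

## Phase-encoded retinotopy

Each vertex of the cortical patch responds to the periodic stimulus as

    y(t) = baseline + A·cos(2πft − φ·direction − δ) + drift + ε,

with *f* = 1/cycle period (36 s eccentricity, 60 s polar by default), φ the
vertex's retinotopic phase, direction ±1 for the two stimulus directions,
and δ = 2πf·(hemodynamic delay) common to both runs. The analysis chain:

1. **Quarter-cycle discard.** The first `round(0.25·period/TR)` samples are
   dropped (transient onset response) and the cycle count reduced by 0.25.
   The run's time origin `t0_s` is advanced accordingly, so Fourier phases
   remain referenced to stimulus onset; without this bookkeeping the discard
   would act as an extra phase offset of π/2 that, combined across opposite
   directions, can null the combined amplitude.
2. **High-pass drift removal.** A DCT-II basis restricted to frequencies at
   or below the cutoff (defaults 1/120 Hz polar, 1/72 Hz eccentricity) is
   fitted *jointly* with cos/sin regressors at the stimulus frequency, and
   only the drift component is subtracted. The joint fit matters: the finite
   DCT basis is not orthogonal to the response over an integer number of
   cycles, and plain drift regression perturbs passband phase by up to
   ~0.016 rad, while the partialled version preserves it to numerical
   precision. A cutoff at or above the stimulus frequency is refused.
3. **Fourier phase.** The complex coefficient `(2/T)·Σ y_t·e^{+i2πft}`
   equals `A·e^{iφ}` for `y = A·cos(2πft − φ)` over integer cycles (the
   documented phase convention). Non-integer cycle counts are computed with
   a leakage warning.
4. **Opposite-run combination.** The reversed-run coefficient is conjugated
   and the complex values averaged; phases `φ + δ` and `−φ + δ` combine to
   phase φ for any δ, with amplitude attenuated by |cos δ|. Complex
   averaging (rather than phase averaging) weights vertices by coherence and
   is robust when the two runs' amplitudes differ. Vertices with zero
   amplitude in both runs are flagged invalid.
5. **Field sign.** Per triangle, in-plane gradients of the two phase maps
   are obtained from the linear interpolant; the sign of the normal
   component of ∇ecc × ∇pol is area-weighted onto vertices. An amplitude
   threshold (default 0 — synthetic data has no unresponsive cortex) zeroes
   unreliable vertices. Field sign is computed and tested but is *not* used
   to delimit V1/V2: the area extent comes from the patch's area labels,
   replacing the manual border drawing of surface-based workflows.
6. **Segmentation.** Per area, phases are min–max scaled to [0, 1]; polar
   splits at 0.5 (upper/lower), eccentricity at 1/3 and 2/3
   (foveal/middle/peripheral); segment id = 1 + polar_bin·3 + ecc_bin
   (+6 for V2). Bins are half-open with the area maximum closing the last
   bin. A constant phase over an area is an error (nothing to scale).

## Synthetic-data generator

The generator provides every pipeline input with known ground truth. It
emulates the *statistical* structure of the study's data, not its anatomy:

- **Patch.** A flat two-band grid (default 17 × 17 vertices, 0.6 mm
  spacing) in the z = 0 plane; eccentricity increases along x in both
  bands, polar angle along y with mirrored slope in V2, so the areas carry
  opposite field signs and matched segments sit adjacent across the border.
  Two deliberate choices: (a) 17 vertices per axis gives even row counts
  per band and 16 column steps, so no ground-truth value falls exactly on a
  bin threshold (on a regular lattice such ties would flip under
  infinitesimal noise and cap segment-recovery rates regardless of SNR);
  (b) 0.6 mm spacing keeps every segment pair's minimum endpoint distance
  in the negligible tail of both length distributions (see below). There is
  no cortical folding: folding changes no formula downstream.
- **BOLD runs.** The sinusoidal model above, with drift = slow half-cosine
  plus linear ramp (per-vertex random coefficients, default amplitude 0.5)
  and white noise. The true phase maps span [0.1, 0.9]·2π so noise cannot
  wrap estimates across 0/2π, which would break min–max scaling.
  `noise_sd_for_amplitude_snr` converts a target single-run Fourier
  amplitude SNR into the time-domain noise SD (`σ·√(2/T)` per coefficient
  component).
- **Label volume.** Each labeled vertex marks its containing voxel (voxel
  size defaults to the vertex spacing, so each vertex owns one voxel); a
  CSF slab spans the full x–y extent at z ∈ [4, 6) mm above the patch.
- **Streamlines.** Cell (i, j) probabilities follow a diagonal-preference
  mixture: a fraction `retino_bias` of the mass is split over the six
  diagonal cells, the rest spread over all 36, giving expected diagonal
  share `b + (1−b)/6` (75% at the default b = 0.7, matching the observed
  ~73% retinotopic share). An explicit 6×6 table overrides the multinomial
  (for exact-count tests). Lengths are drawn from truncated normals on
  [3, 100] mm — 16 ± 4 mm for diagonal, 32 ± 13 mm for off-diagonal cells —
  then endpoints are sampled uniformly inside the target segments' voxels
  (jittered within-voxel, so endpoint assignment round-trips exactly) and
  resampled until feasible (length ≥ endpoint distance); the drawn length is
  kept fixed during resampling so the length distribution is unbiased except
  where a draw falls below a cell's minimum chord, which the 0.6 mm patch
  scale makes negligible. Each streamline is a circular arc through its
  endpoints (half-angle solved from arc length/chord), bulging away from the
  CSF slab, sampled at 0.2 mm steps. A `csf_contaminant_fraction` of
  streamlines instead arcs upward through the CSF slab and is tagged.
- **b = 0 series.** Voxel mean fixed; temporal SD set so tSNR follows the
  coil profile: uniform, or a surface profile decaying from the coil face
  with a configurable near/deep ratio (default 1.7) through a linear ramp
  between distance bands; the band ROIs are exposed as presets.
- **Determinism.** All randomness derives from `GeneratorConfig.seed`
  through fixed-offset child streams; identical configs give bit-identical
  output.

What the generator does **not** emulate: cortical folding, partial-volume
and registration error between functional and diffusion spaces, tractography
false positives/negatives beyond the CSF contaminants, spatially correlated
or non-Gaussian noise, and scanner artifacts. Passing tests therefore
demonstrate correctness of the quantification and inference chain under the
declared statistical model, not robustness to real-data confounds.

## Connectivity quantification

Endpoints are assigned to the voxel containing them (inverse affine,
`floor(v + 0.5)`, voxel centers at integer coordinates); there is no
dilation or nearest-label search, and external tractograms must satisfy this
convention. Retention requires one endpoint in V1 and one in V2 (same-area
pairs are discarded); any point in a CSF voxel — including an endpoint —
discards the streamline. Percentages are normalized to the hemisphere's
total retained count and sum to 100 exactly. The proximity matrix averages
1/L per cell over retained streamlines, with zero-length streamlines
excluded via the log and empty cells flagged undefined rather than given a
value. Group averages are element-wise means with pairwise exclusion of
undefined cells (defined-count recorded).

The U-shape filter retains streamlines with arc length ≤ 25 mm (default)
and total turning angle — the sum of successive inter-segment angles, the
operationalization chosen for a cumulative "curvature threshold" — ≥ 90°.
Both thresholds are explicit parameters.

## Inference

- **Restricted permutation test.** The retinotopic/non-retinotopic totals
  of a hemisphere sum to 100 (percent units), so the natural test is a
  paired t on within-hemisphere differences; swapping the two totals within
  a hemisphere is exactly a sign flip of its difference. All 2^H
  assignments are enumerated (identity included; H ≤ 20), and
  p = #(t_perm ≥ t_obs)/2^H, ties counting toward p. With H = 6 the
  achievable p values are multiples of 1/64 and the minimum is ≈ 0.0156.
  Zero-variance flip patterns yield a signed-infinity t sentinel rather than
  an exception, and sentinels compare by value in the tally.
- **ICC.** ICC(2,1) — two-way random effects, single measure, absolute
  agreement — computed per matrix cell across hemispheres with the two
  measurements as raters, from the closed-form mean-squares expression.
  Cells with no variance at all or zero between-hemisphere variance are
  flagged undefined. The choice of form is recorded in the output; the
  literature often reports bare "ICC", and ICC(2,1) is the standard choice
  for scan–rescan agreement in absolute units.
- **CoV.** Default: per hemisphere-cell, sample SD of the two measurements
  over their mean, averaged across hemispheres (`across_measurements`).
  The alternative aggregation (`across_hemispheres`: SD/mean over
  hemispheres per measurement, then averaged) is implemented and selectable;
  the two answer slightly different reproducibility questions and the
  default follows the scan–rescan reading.
- **ANOVA.** Classical 2×2 within-subject decomposition on absolute counts
  (type × coil), each effect tested against its own effect-by-subject
  interaction with df = (1, H−1). Zero error variance with a nonzero effect
  yields the +inf sentinel (p = 0); all-constant data give F = 0. Missing
  cells are an error — no imputation.
- **Motion QC.** Two-tailed paired t per motion parameter (3 translations,
  3 rotations) on per-participant SDs, same sentinel contract.

When the demo simulates several hemispheres it draws each hemisphere's true
diagonal-mass fraction from a truncated normal (SD 0.05) around the
configured bias. This emulates between-subject variability; without it every
hemisphere shares one true connectivity profile and ICC — which compares
between-hemisphere to within-hemisphere variance — is degenerate near zero
by construction. Analyses that prescribe identically distributed hemispheres
(power and type-I-error studies) use the fixed bias.

## Problem sizes and numerical choices

The test suite and acceptance script run the study at desk scale, chosen as
the package's own defaults: 6 hemispheres × 1000 streamlines × 2
acquisitions for the end-to-end study; 3000-streamline draws for moment
checks; 500 count-level replicates for the power (bias 0.7 → rejection in
≥ 95%) and type-I-error (bias 1/6) studies — cell assignment is exactly
multinomial in the generator, so count-level simulation reproduces the
test's rejection behaviour without arc geometry; 100–500 volumes for tSNR
convergence. Segment-recovery rates at amplitude SNR 10 are evaluated as a
mean over five seeds (a single realization fluctuates ±2 percentage points
around its ~96% mean).

Tie-breaks and degenerate inputs: segment bins are half-open with the area
maximum in the last bin; endpoint voxel assignment uses `floor(v + 0.5)`;
degenerate (zero-area) triangles are skipped in field sign with a log
entry; zero-amplitude vertices, empty proximity cells, and undefined
ICC/CoV cells are flagged rather than silently valued; all-zero difference
vectors refuse the permutation test. The arc half-angle equation
`θ/sin θ = L/c` is solved by bracketed root finding on (0, π); `L ≤ c`
degenerates to the straight segment.

## Known limitations

- The flat patch cannot exercise surface-to-volume registration error or
  folding-dependent tractography failure modes.
- The permutation test's granularity at H = 6 (p multiples of 1/64) means
  "significant at 0.05" is equivalent to p ∈ {1/64, 2/64, 3/64}; power
  statements are about this discrete test.
- ICC values from the demo depend on the assumed between-hemisphere
  variability (SD 0.05 of the bias); real between-subject variance is not
  identifiable from the generator.
- The U-shape turning-angle criterion is one of several possible curvature
  measures; results for strongly kinked polylines depend on the sampling
  step.
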