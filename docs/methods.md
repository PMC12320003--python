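# Methods

`laminapipe` preprocesses high-resolution resting-state fMRI series and
analyses functional connectivity on an atlas hierarchy down to cortical
layers. Every stage is validated on a synthetic layered brain phantom with
exact ground truth; this note records the models, the defaults, the numerical
choices, and what the phantom does and does not establish.

## Thermal-noise model and RMT-PCA denoising

High-resolution EPI is thermal-noise dominated. We model the noise as i.i.d.
Gaussian on magnitude images (the high-SNR approximation of Rician noise)
with a spatially varying but temporally stationary standard deviation σ.

Each in-plane 3×3 patch of the series is unfolded into a Casorati matrix
`X ∈ R^{P×T}` (P = 9 patch voxels, T = time frames; patches never span
slices). After removing each voxel's temporal mean, the singular values of
`X/√(T−1)` under pure noise follow the Marchenko–Pastur (MP) law with aspect
ratio γ = P/(T−1); the largest noise singular value fluctuates around the
bulk edge σ(1+√γ) on the Tracy–Widom (TW1) scale. With T ≈ 310 ≫ P = 9 the
TW distribution is narrow, so the signal/noise split is sharp.

* **σ estimation.** σ̂ = median(noise-bulk singular values) / √(MP median at
  γ). The MP median is computed by numerically inverting the MP CDF. The
  median matching is robust to a few signal spikes; split and σ̂ are
  alternated until the spike count stabilises.
* **Threshold.** `mp_edge` uses the deterministic bulk edge; `tw_quantile`
  (default, level 0.95) targets the TW1 quantile of the largest noise
  singular value. Because σ̂ itself is estimated from only P bulk values,
  plugging it into the asymptotic TW quantile (standard Johnstone
  centering/scaling, quantiles interpolated from tabulated values) is
  slightly anti-conservative; the edge multiplier of the self-normalized
  statistic is therefore calibrated once per (P, T, level) against a seeded
  simulation of the exact null, fixing the per-patch false-signal rate at
  the nominal level. Ties at the threshold are classified as noise.
* **Signal shrinkage.** Retained components are themselves noise-inflated.
  Each kept eigenvalue y (in σ̂² units) is inverted through the spiked-model
  relation y = (1+ℓ)(1+γ/ℓ) and replaced by σ̂√ℓ, i.e. the estimated
  noise-free singular value. This debiasing is a documented standard choice;
  simulations in the test suite show it strictly beats hard truncation in
  mean squared error on planted low-rank signals.
* **Aggregation.** Patches slide with stride 1; overlapping estimates are
  averaged uniformly (optionally weighted by each patch's retained-component
  count). `denoised + residual == input` holds exactly by construction, and
  the whole operation is equivariant to global intensity scaling.

The residual is pooled and tested for Gaussianity (Anderson–Darling with the
D'Agostino adjustment for estimated parameters): on a pure-noise phantom the
residual passes; on real data structured residuals would indicate signal
leakage.

## Motion estimation

Three stages, fixed order, each estimating on the residual of the previous
one; images are resampled only into throw-away working copies, never into
the output path.

1. **Per-slice PE translation (pe2d).** Scanner instability shows up as a
   slice-dependent translation along the phase-encode axis. Each slice is
   registered to the reference by windowed (Hann) phase correlation with
   upsampled sub-pixel refinement (factor 100) and one window-redisplacement
   iteration to remove taper bias; only the PE component is kept. This
   stage is optional — the drift may be instrument-specific.
2. **Volumetric rigid (rigid3d).** 6-DOF least-squares intensity criterion,
   trust-region solver over the voxel residual vector, coarse (smoothed,
   linear interpolation) then fine (cubic) pass. A border margin is excluded
   so fill values cannot bias the fit. On slabs thinner than 8 slices the
   out-of-plane parameters (tz, rx, ry) are unidentifiable and are frozen by
   default. Rotation convention: intrinsic x→y→z, degrees, about the grid
   centre; translations in mm.
3. **Non-rigid patch (nonrigid).** Raised-cosine-tapered patches (default
   24 voxels, stride 8) are registered by Fourier phase correlation with
   sub-pixel upsampling and window redisplacement; patch-centre shifts pass
   a median-test outlier validation (threshold 0.75 voxel, standard PIV
   practice), are smoothed, spline-interpolated, and extended beyond the
   patch-centre hull by a capped first-order Taylor step. A second pass
   re-estimates the residual with smaller patches after warping a working
   copy, and is skipped when the field is below the ≈0.2-voxel noise floor
   of patch phase correlation on smooth texture.

All estimates are stored in the *pullback correction* convention: resampling
the frame with the stored transform aligns it to the reference. The
`estimate_pe_translation_2d` return value alone follows the content
convention (a +3-voxel content shift yields −3), mirroring how such traces
are usually plotted; the stored per-slice shift is its negation.

## Distortion correction and one-pass resampling

The B0 field map (Hz) converts to a PE-axis voxel displacement as
`shift = field × effective echo spacing × n_PE × polarity`. The resulting
distortion map is inverted numerically (fixed-point iteration, tolerance
0.01 voxel, max 50 iterations) to obtain the correction field.

All correction sources — B0, per-slice PE, rigid, non-rigid, plus any output
grid change (upsampling, corner-aligned) — are composed *functionally* (the
total map is the composition of the source maps, not their sum) into one
displacement field per frame, and the data are interpolated exactly once
(instrumented: tests count interpolations). Composition order is the inverse
of the physical forward order (B0 → PE → rigid → non-rigid). Resampling is
pullback/output-driven; integer mappings short-circuit to exact gathers, so
identity and whole-voxel shifts are lossless. Interpolants: linear, cubic
spline (default), and Lanczos-3 windowed sinc. Out-of-field voxels are set
to 0.

Smoothness is tracked as the FWHM of the equivalent Gaussian kernel,
estimated per axis from the variance of spatial first differences relative
to total variance (ρ = 1 − VarΔ/2Var, σ² = −1/(4 ln ρ), FWHM = √(8 ln 2)·σ),
geometrically averaged over axes; smoothing white noise with a kernel of
FWHM w reports ≈ w, and white noise reports 0. The single-pass design keeps
FWHM strictly below sequential per-source resampling with the same kernel.

## Nuisance cleaning

Voxel-wise least-squares regression of the six rigid parameters plus a drift
basis (default: DCT cosines below 0.01 Hz; `floor(2·duration·cutoff)`
regressors), followed by zero-phase 4th-order Butterworth band-pass into
0.01–0.1 Hz — the infra-slow band carrying spontaneous BOLD fluctuations.
Regression runs first, with motion regressors band-pass matched beforehand,
so filtered-out frequencies cannot re-enter through the regression. Voxel
means are restored after regression; the band-pass removes them (unless the
low cut is 0). Global-signal regression is off by default.

## Alignment

Bias correction fits a degree-3 polynomial to log intensities inside the
mask and divides out its exponential, normalised to unit geometric mean
(hence invariant to global scaling). Brain masking is Otsu threshold →
largest connected component → in-plane morphological closing → hole filling;
it need not be perfect. Linear registration (rigid 6-DOF or affine 12-DOF;
correlation or 32-bin mutual information) is a multi-resolution Powell
search, registering the texture-rich image onto the poorer one (anatomical →
EPI rigid; atlas → anatomical affine); on thin slabs rigid registration is
restricted to in-plane parameters. Non-linear refinement offers an external
symmetric-normalization backend when the optional `ants` package is present
and an internal multi-resolution diffusion-regularized demons solver
(Gaussian smoothing of update σ=1.0 and field σ=1.5 voxels, force
stabiliser α²=0.05) that keeps the package self-contained; full
diffeomorphic machinery is deliberately out of scope. Transform chains
compose linear steps and displacement fields into a single field (labels are
resampled nearest-neighbour only) and every chain has a numerically
computable inverse.

## Hierarchical connectome

A seed's time course is the unweighted voxel mean over the region *and all
its descendants* — the whole-structure average, not a mean of child means,
so parent and child seeds are mutually consistent. Connectivity is Pearson r
Fisher-transformed to z = atanh(r), with |r| clipped at 1−10⁻⁷ so
self-correlation stays finite; matrix diagonals carry NaN as the documented
sentinel. Connectograms list undirected edges with z above threshold
(default 0.2) sorted by |z|. Seed-size scaling fits OLS slopes of
log₁₀(mean suprathreshold z) and log₁₀(suprathreshold count) against
log₁₀(seed voxels); seed voxels are excluded from suprathreshold accounting
by default (self-correlation would inflate it; a flag restores inclusion).
Group averaging is a voxel-wise mean in the Fisher domain with an optional
one-sample t map.

## The phantom: what it emulates, what it does not

The phantom mirrors the study conditions: 96×48 in-plane matrix (0.25 mm),
up to 9 slices, 310 frames at TR = 1 s; cortical layer volumes proportional
to the barrel-field laminar thicknesses (0.12/0.25/0.20/0.27/0.32 mm of a
1.16 mm ribbon, assigned by depth-rank quantiles so the proportions hold
within rounding); white-matter band and subcortical core; hemispheric split;
a 3-level region → subregion → layer hierarchy. BOLD-like signals are
band-limited (0.01–0.1 Hz) unit-SD region courses Cholesky-mixed to a
planted correlation matrix, with 10 % voxel-level jitter, riding on the
anatomical contrast rescaled to a baseline of 100. Thermal noise defaults to
σ = 10 (tSNR ≈ 10 before denoising, a thermal-noise-dominated regime); the
true noise level of real acquisitions is not claimed. The acquisition model
applies, in fixed forward order, non-rigid deformation → rigid motion
(predominantly in-plane, as for a head-fixed animal) → per-slice PE drift →
B0 distortion (±30 Hz) → noise, composed into a single resampling per frame.

Not emulated: k-space/EPI readout physics, T2* decay, physiological
(cardiac/respiratory) noise, Rician noise at low SNR, receive-coil
g-factors, inter-subject anatomical variability. Passing tests therefore
demonstrate the *algorithms* recover known truth under the stated noise and
motion model, not that real-data gains will match numerically.

## Problem sizes and tolerances in the validation suite

The test suite and the acceptance script regenerate everything at desk
scale: phantoms of 48×32–64×48 in-plane voxels, 1–3 slices, 40–600 frames
for staged runs, 5000 frames for connectivity sampling checks, 1000
replicates for the null-calibration rate, and 20 seeded replicates for
parameter recovery. Band-limited signals carry ≈ 2×(0.1−0.01)×T effective
samples, which sets the Fisher-z standard errors the recovery checks use.
Directional claims (tSNR gain, correlation gain after distortion correction,
staged-correlation monotonicity, single- vs multi-pass FWHM) are asserted as
orderings; published magnitudes from any particular acquisition are
data-specific and are not asserted.

## Known limitations

* Patch phase correlation has a ≈0.2-voxel noise floor on low-texture
  content and suffers from the aperture problem on locally 1-D structure.
* The demons refinement is small-deformation only; large or topology-
  changing warps need the external backend.
* The per-slice PE stage assumes the drift is a pure translation per slice.
* Rician bias at low SNR is not modelled; σ̂ would be biased where the
  Gaussian approximation fails.
* The spiked-model shrinkage assumes white noise within a patch; coloured
  noise (e.g. residual physiology) violates the MP null.
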