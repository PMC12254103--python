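# Methods

## Phantom model

The NEMA-IEC body phantom is modeled as an elliptical-cylinder body
compartment (default semi-axes 150 × 115 mm, interior length 180 mm,
volume metadata 9.7 L) filled with background activity concentration
`B_in` (default 2.0 kBq/mL), containing six filled spheres of inside
diameters 10, 13, 17, 22, 28 and 37 mm at `T_in = TBR · B_in`. Sphere
walls are ignored — only inside diameters are known — and the spheres sit
on the standard 57.2 mm-radius ring in one transaxial plane. The analytic
sphere volumes reproduce the nominal set (0.5, 1.2, 2.6, 5.6, 11.5,
26.5 mL) to one decimal.

Axis convention: axis 0 = x (left–right), axis 1 = y
(anterior–posterior), axis 2 = z (inferior–superior; the motion axis).
A voxel's coordinate is its center; indexing is 0-based.

Prepared activities are decay-corrected to scan initiation with the ¹⁸F
half-life (109.77 min) when a calibration-to-scan interval is configured;
the same decayed values enter both the simulated image and the RC
denominator, which is what a correctly decay-corrected physical
measurement does.

### Rasterization

Voxels fully inside a sphere receive `T_in`, voxels inside the body
`B_in`, voxels outside the body 0. Voxels cut by a boundary are subdivided
`supersample³` times (default 4³ = 64) and assigned the sub-volume
fraction; the rasterized 37 mm sphere volume agrees with the closed form
within 1%. A sphere extending beyond the grid is an error naming the
sphere, not a silent crop.

## Acquisition emulation

1. **Motion blur.** The platform moves the phantom back and forth at
   constant speed over a total range of A mm (amplitude = peak-to-peak
   travel). Constant speed with instantaneous turnarounds gives a uniform
   positional dwell density on [−A/2, +A/2], independent of the speed and
   period, so the blur kernel is the uniform density integrated over each
   voxel pitch along z: interior taps get `pitch/A`, the two end taps the
   remainder. The nominal 4 s period and 0.75 cm/s speed are stored as
   metadata only; they are mutually inconsistent for most amplitudes (a
   30 mm range at 0.75 cm/s takes 8 s per cycle) and neither enters the
   kernel. Discretization was checked against a 10⁵-step time-stepped
   trajectory oracle.
2. **Scanner PSF.** Isotropic Gaussian with σ = FWHM / (2√(2 ln 2)),
   default FWHM 5 mm, emulating the reconstruction post-filter (the
   package models no reconstruction; the post-filter dominates the
   resolution of the final image).
3. **Noise.** Additive Gaussian noise (default level 0.15 kBq/mL on the
   2.0 kBq/mL background, ≈7.5% background coefficient of variation —
   chosen once as a plausible post-reconstruction noise magnitude) or a
   scaled-Poisson model with variance proportional to the signal. Real
   post-reconstruction PET noise is spatially correlated; neither model
   reproduces that texture, so noise-dependent results are directional,
   not calibrated.

Both convolutions use reflective boundaries (recorded in image metadata),
which preserve total activity exactly for symmetric kernels; the pipeline
conserves activity to better than 10⁻³ with the phantom away from grid
edges. With A = 0 the kernel is a single unit tap and the moving pipeline
equals the static pipeline bit-exactly.

## VOI identification

The target VOI is a *cube* of half-width r_s (the sphere radius): the
defining average runs over a coordinate box, not a ball. Users comparing
with spherical EARL-style VOIs should expect lower means for hot spheres.
Per axis, the half-width in voxels is `round(r_s / pitch)`
(half-away-from-zero, minimum 1 voxel). A VOI that would leave the image
is an error, never clipped.

The initial midpoint (in batch mode, the voxel nearest the true sphere
center — the simulated "click") is refined exhaustively over ±5 voxels in
x and y and ±3 slices in z (847 candidates; the smaller z range reflects
the coarser through-plane sampling), keeping the candidate with maximal
VOI mean. Ties are broken by smallest Euclidean index distance to the
initial guess, then lexicographically, so the search is deterministic; it
is verified equivalent to an independent brute-force scan. The rigid cube
underestimates activity for strongly blurred targets — inherent to the
method being modeled, not corrected here.

The background VOI reuses the largest sphere's half-width (18.5 mm) at a
fixed, configurable left-posterior position (default center (−80, −52, 0)
mm from the phantom center), chosen so the cube lies fully inside the body
compartment, geometrically clear of every sphere, and far enough from the
body's axial caps that motion blur of the caps cannot reach it. The
position is never optimized. σ_B is the sample standard deviation (n − 1).

## Endpoints and aggregation

RC and CNR are computed per record exactly as defined in the README;
`RC_max ≥ RC_mean` always, and CNR may be negative. With/without ratios
are computed per (sphere, amplitude) cell per TBR and then averaged —
mean of ratios, not ratio of means, which keeps each TBR's cell a valid
paired observation. A TBR cell whose with- or without-correction value is
negative is excluded from the average and listed; a cell with no
survivors is flagged undefined (NaN) rather than invented.

The background-noise change is 100·(σ_with − σ_without)/σ_without per
(TBR, amplitude), averaged over amplitudes per TBR. Two overall summaries
are reported — the mean of per-TBR means and the plain mean over all
cells — because the aggregation order changes the value slightly and the
choice is not obvious a priori.

On noise-free images σ_B can be numerically zero; CNR is then flagged NaN
on the record (the strict `contrast_to_noise` operation still raises),
and downstream aggregation and statistics skip the undefined endpoint
explicitly.

## Correction surrogate

Real data-driven motion correction estimates a deblurring kernel from the
data inside a proprietary reconstruction. The surrogate instead
deconvolves the *known* simulation kernel along the motion axis:
Richardson–Lucy-type multiplicative iterations (default 25; non-negativity
preserved; negative noise excursions clipped to zero for the iteration, as
the underlying likelihood model requires) or a Wiener-regularized spectral
inverse. Defaults were chosen so the surrogate exhibits both faces of
deconvolution on the default phantom: restored sphere peaks (a 13 mm
sphere blurred by 20 mm of motion recovers its static peak within 5% after
50 iterations) and amplified background noise. The surrogate's oracle
advantage — it is handed the exact kernel — means absolute effect sizes
are optimistic; directions and trade-offs are the meaningful output. With
an identity kernel (amplitude 0) the correction is an exact no-op, so
every static with/without ratio is exactly 1; consequently the
noise-amplification property holds for moving cells only, unlike a real
scanner chain where even static reconstructions differ.

## Statistical protocol

Records are paired on (sphere, amplitude, TBR); the default design gives
n = 90 pairs per parameter. Per parameter (RC_max, RC_mean, CNR_max,
CNR_mean) the differences pass a Shapiro–Wilk gate at α = 0.05 (a
quantile–quantile table is emitted for visual checking): normal →
paired t-test, otherwise Wilcoxon signed-rank. Wilcoxon conventions, none
of which are forced by the method being modeled and all of which are
therefore stated: zero differences dropped (n reported after dropping),
W = smaller of the two signed-rank sums, exact null distribution for
n ≤ 25 without ties, tie-corrected normal approximation without
continuity correction above. The implementation rides on scipy; tests
verify it against a hand-rolled signed-rank oracle and R's `wilcox.test`.
No multiplicity correction is applied across the four parameters.

## Problem sizes and determinism

The default grid is the phantom bounding box plus a 3 cm margin at the
scanner's voxel sizes (500/440 ≈ 1.136 mm in-plane, 2 mm slices), about
318 × 257 × 121 voxels — the package's desk-scale default; a full
440 × 440 matrix is selectable by config. The test suite uses compact
three-sphere phantoms (~140³ voxel grids) so the whole suite runs in well
under a minute; the acceptance script runs the full default design in a
few minutes. Every stochastic stage derives its seed from the master seed
and the cell's design position via `numpy.random.SeedSequence`, making
every output table byte-reproducible.

## Known limitations

* 1-D rigid translation only: no rotation, hysteresis, baseline drift or
  irregular breathing; no attenuation, scatter, randoms, or
  reconstruction — the simulation starts at a post-reconstruction image.
* Uncorrelated noise models; real reconstructed noise texture is
  correlated and scanner-dependent.
* The surrogate is not OncoFreeze (AI): effect sizes are not comparable
  to scanner measurements, only directions and the structure of the
  analysis are.
* The VOI search assumes the true center is within the search range of
  the initial guess; gross mis-clicks are out of scope.
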