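# Methods

## Signal model and T1 estimation

The acquisition is a magnitude inversion-recovery series with fixed
repetition time: seven images at TI = 50, 150, 350, 700, 1050, 1400 and
2000 ms, TR = 1800 ms, TE = 13 ms. The model fitted per pixel is

    S(TI) = S0 · | 1 − 2 exp(−TI/T1) + exp(−TR/T1) |

with two free parameters (S0, T1). Inversion efficiency is fixed at 2
(perfect inversion) and the echo-time weighting is a constant
multiplicative factor at fixed TE, so it is absorbed into S0 rather than
modelled; this is the smallest parameterization consistent with a
fixed-TR IR acquisition. Consequences: a uniform intensity scale on a
series changes S0 only, leaving T1 invariant (tested), and B1/inversion
imperfections are not estimated (out of scope).

The residual sum of squares is minimized by the Nelder–Mead simplex.
The magnitude model has a null point near TI ≈ T1·ln 2 that creates
local minima, so the simplex is seeded with S0 = max(signal) and the
best T1 on a coarse grid of 200–2000 ms in 100 ms steps. Parameters are
rescaled by their initial values inside the optimizer so that the
simplex tolerance of 1e-6 acts relatively (the underlying scipy
tolerances are absolute); the iteration cap is 2000. A fit is reported
non-converged when the cap is hit, and an all-zero signal vector is
flagged without fitting. Noiseless round-trips recover T1 to well under
0.1 ms across 300–1600 ms (tested).

Fitted T1 values outside the 400–1500 ms acceptance window are marked
invalid before any averaging; the window bounds are configurable in the
pipeline. Subcutaneous fat (≈380 ms at 3 T by default — a configuration
knob, to be set per scanner, not a literature constant) therefore never
contaminates disc statistics even when fat pixels fall inside a fitted
region.

## Fat-reference normalization

Some series are recorded with the scanner's automatic per-image
intensity normalization left enabled, which multiplies each of the
seven images by an unknown positive scale and destroys the IR curve.
Fat T1 is unchanged by the contrast agent and constant over the study,
so the observed per-image fat means f_i must be proportional to the
model curve e_i = |1 − 2e^(−TI_i/T1_fat) + e^(−TR/T1_fat)|. The fat
amplitude is estimated by least squares, Ŝ = (Σ f_i e_i)/(Σ e_i²), and
image i is multiplied by factor_i = Ŝ·e_i/f_i, which places the fat
means exactly on the expected curve. For an uncorrupted series all
factors coincide (a harmless global scale); for a corrupted one,
factor_i × corruption_i is constant, and the corrected disc T1 matches
the clean fit to <0.1 ms in the noiseless case (both tested). The
correction is deliberately not idempotent; re-application warns.
Because the simulator and the corrector share the configured fat T1, the
round-trip guarantees hold for any plausible fat T1 setting.

## Disc geometry

The disc boundary is an ellipse fitted to eight manually placed
landmarks by the direct least-squares conic method with the ellipse
constraint (via scikit-image's `EllipseModel`); points lying exactly on
an ellipse recover its parameters to 1e-6, and eight points with 0.5 px
isotropic jitter recover the semi-axes within 0.5 px (fixed-seed test).
Degenerate input (fewer than 5 points, collinear points, non-elliptical
conic) raises a typed error. Landmark files carry the index of the
anterior landmark; the anterior midline direction is the ray from the
fitted center through that point.

Pixels map to normalized elliptical coordinates: translate by the
center, rotate by the orientation, scale the axes to the unit circle;
ρ = √((x′/a)² + (y′/b)²), and θ is measured counterclockwise from the
anterior direction mapped into the same normalized frame. The 60
sectors are 5 rings of equal normalized radius (ring k: ρ ∈
[(k−1)/5, k/5)) × 12 wedges of 30° with wedge 0 centered on the
anterior midline. The 5 × 12 factorization is the one consistent with a
five-ring nucleus/annulus layout; equal-radius (not equal-area) bands
were chosen to match the rendered geometry of such sector maps, giving
ring areas in the ratio 1:3:5:7:9 (verified to 2 % on a 512² grid).
Deterministic tie-breaks: a ρ exactly on a band boundary goes to the
outer ring, a θ on a wedge boundary to the higher wedge index, and the
center pixel (θ undefined) to wedge 0. Conventions: 0-based (row, col)
pixel indices, pixel-center sampling, angles in degrees with x = col,
y = row.

Rings 1–2 form the nucleus pulposus, rings 3–5 the annulus fibrosus.
Anterior and posterior zones default to 90° windows (3 wedges) of the
annulus only; the window width is configurable. All rings are wedge-
subdivided internally; for ring-level statistics this is equivalent to
leaving the innermost ring undivided.

## Aggregation

ΔT1 = native − post-contrast is computed pixel-wise on the intersection
of the two validity masks; maps must agree on subject, disc and
timepoint, or pairing fails. Regional statistics (per sector, ring,
nucleus/annulus, anterior/posterior, whole disc) are valid-pixel-
weighted: slices of a disc are pooled at the pixel level (two slices by
default), so the disc mean over a fixed mask equals the difference of
the native and post-contrast means on that mask exactly, and every
roll-up is a convex combination of its sector means. Regions without
valid pixels are reported missing (n = 0, NaN), never as zero. The sd
uses the sample (n−1) denominator throughout. An unweighted-sector
alternative was considered and rejected because it makes disc means
depend on the sector grid rather than on the measured pixels; with
pooling weights unknown for historical tables, study-level grand
averages are not constructed from per-region means at all.

GAG content is estimated from ΔT1 with the published linear calibration
against biochemically assayed glycosaminoglycan, GAG [µg/mg] =
−1.38·ΔT1 + 238, applied unchanged; no correction is attempted for
post-injection delay differences between protocols.

## Statistics

The study table is long-format (subject, disc level, timepoint, measure,
region, mean/sd/n). Factorial fixed-effects ANOVA with all interactions
is fitted by OLS; Type II sums of squares are used, which for the
balanced designs produced here coincide with the classical decomposition
and are invariant to factor order. Aliased factors (rank-deficient
design) and designs without residual degrees of freedom raise typed
errors; at desk scale (one subject) the pipeline records the skipped
ANOVA in the run manifest instead of failing. Tukey HSD is run per
significant factor at α = 0.05 using the one-way residual mean square:
q = |Δ| / √(MSE/2·(1/n₁+1/n₂)) with p from the studentized-range
distribution; results match statsmodels' implementation to 1e-6 (tested
as an independent cross-check). Subject can be included as a factor or
pooled; both usages are supported and the choice is left to the analyst.

## Synthetic phantoms

The generator emulates the study material: an elliptical disc with
ring-structured T1 (defaults: healthy pre-bedrest ring means, native
1131.38/1007.97/916.16/680.31/532.66 ms, with matching post-contrast
and post-bedrest vectors), a rectangular fat region of known T1
disjoint from the disc, zero background, seven-point IR simulation at
the protocol TIs, additive zero-mean Gaussian noise on the magnitude
signal (sd as a fraction of S0; 2 % by default) followed by taking the
magnitude, an optional Rician mode (magnitude of complex Gaussian,
off by default since the Gaussian model is adequate at these SNRs and
keeps the noise interpretable), and optional per-image auto-scaling
factors reproducing the normalization defect. Landmarks sit at fixed
parametric angles 0°, 45°, …, 315° with optional jitter. The bedrest
intervention is represented purely as different ring-T1 vectors per
timepoint; no biophysical model of GAG or water kinetics is attempted.
Slices of a disc are independent replicate grids (slice-to-slice
correlation is not modelled). All randomness flows from explicit seeds
through numpy `SeedSequence`s; identical seeds give bit-identical
arrays.

What the phantoms do not emulate: anatomical shape (discs are perfect
ellipses), partial-volume effects at boundaries, B0/B1 field
inhomogeneity, motion between TIs, imperfect inversion, and spatially
correlated noise. Passing tests therefore demonstrate the correctness
of the estimation chain under its own model assumptions, not robustness
to every artefact of scanner data.

## Problem sizes and defaults

The default phantom grid is 128×128 with a 40×24 px semi-axis ellipse
(~3000 disc pixels), a desk-scale stand-in for the 512×512 acquisition
matrix; protocol geometry is configurable and the field of view is
metadata. Unit tests use 48²–64² grids (200–600 disc pixels) so the
pixel-wise simplex fits stay fast; the recovery checks use the full
128² phantom. End-to-end recovery at 2 % noise is asserted within three
standard errors of the pixel-level estimate, the natural sampling
tolerance for a mean over ~3000 independent pixel fits (the small
magnitude-noise bias of the fit lies inside this band at this SNR).

## Known limitations

- Single-component T1 only; no T2/T2* estimation, no spatial
  regularization, no B1 or inversion-efficiency mapping.
- The fat reference T1 must be supplied per scanner/field strength; the
  380 ms default is a placeholder configuration value.
- No DICOM ingestion; series enter as NIfTI + JSON sidecars.
- Mixed-effects / repeated-measures modelling is out of scope; the
  factorial ANOVA treats observations as independent.
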