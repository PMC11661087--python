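# Methods

## The measurement model

A membrane-localized fluorophore labels an axon's plasma membrane, not
its lumen, so a thin axon imaged in a single confocal plane appears as
two bright, nearly parallel boundary lines.  An intensity profile taken
perpendicular to the center axis therefore shows two peaks, and the
distance between them estimates the local caliber (diameter).  In the
ideal limit the profile of a tube of diameter d under a Gaussian PSF of
standard deviation σ is

    I(x) = exp(−(x − d/2)² / 2σ²) + exp(−(x + d/2)² / 2σ²),

which the package exposes as `analytic_linescan_profile` and uses as the
independent oracle for both the renderer and the peak detector.  Two
equal Gaussians merge into a single mode when d < 2σ; below that
separation no caliber exists to be read from the profile, which is why
measurements are flagged (`single_peak`, `below_resolution`) rather than
extrapolated.

The estimator: bilinear interpolation along the scan line, optional
Gaussian pre-smoothing (default 1 pixel; disabled in oracle tests),
`scipy.signal.find_peaks` with a prominence threshold of 10% of the
profile range, selection of the **nearest** qualifying peak on each side
of the centerline crossing (robust to brighter neighboring structures in
the scan window), and 3-point parabolic sub-pixel refinement of each
peak.  A same-side competitor within 10% of the chosen peak's height
sets an `ambiguous_peaks` flag without changing the choice.

Coordinates are continuous micrometers with pixel centers at integer
multiples of the pixel size; this makes the interpolation identity
(scanning through pixel centers returns pixel values exactly) hold and
keeps every module interface in μm.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pixel_size | 0.04 | μm/px | Nyquist-satisfying sampling for the PSF below |
| psf_fwhm | 0.14 | μm | lateral resolution scale of Airyscan-class detection |
| membrane_amplitude | 100 | photons | peak SNR ≈ √100 = 10 with shot noise on |
| scan_half_length | 1.5 | μm | covers calibers up to ~1.5 μm plus background |
| scan_step | pixel/2 | μm | sub-pixel profile sampling |
| peak_prominence_fraction | 0.1 | — | rejects noise peaks at SNR ≈ 10 |
| resolution_limit | 0.14 | μm | configurable; flags, never drops silently |
| branch_exclusion | 3 (5 for symmetry) | μm | keeps scans clear of branch-point geometry |
| frame_interval | 5 | min | the imaging cadence the dynamics statistics assume |

The resolution limit deserves emphasis: it is an explicit, configurable
parameter.  Measurements below it are excluded from means but still
counted for the cohort exclusion rule that discards an axon when more
than 20% of its baseline measurements are unresolvable.

## Synthetic scenes: what they emulate and what they do not

The generator deposits fluorescence along the two boundary curves offset
±r(s) along the centerline normal (uniform arc-length sampling at 1/5
pixel, bilinear splatting), convolves with an isotropic Gaussian PSF,
scales the peak to `membrane_amplitude`, and adds background, Poisson
and Gaussian read noise.  Radius profiles are constant, Gaussian-pearled
(r(s) = base + Σ aₖ·exp(−(s−sₖ)²/2wₖ²)), or sinusoidal; scripted
behaviors cover a traveling pearl, focal inflation/deflation, uniform
segment widening/narrowing, and a toggled constriction point; division
scenarios script the planar contraction and rebound of a dividing cell's
borders, with optional caliber increase on the dividing span, round→flat
thinning, pearl-amplitude changes, and a second equal contraction to
exercise tie-breaking in frame selection.

Deliberately absent: 3D rendering (the vertical dimension of the
rounding cell exists only in the geometry model), deconvolution
artifacts, photobleaching, focus drift, neighboring-cell texture, and
annotation error — real centerlines are hand-drawn, synthetic ones are
exact.  Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated optical model, not robustness to
annotation noise or out-of-focus light.

## Statistics

Paired comparisons use a permutation test with statistic mean(d) and a
null of independent sign flips: exhaustive over all 2ⁿ assignments for
n ≤ 20 (a meet-in-the-middle split keeps n = 20 at ~1M sums), Monte
Carlo with the identity assignment in the denominator above that, so
p ∈ (0, 1] always.  All-zero differences return p = 1 with a degenerate
flag.  Population comparisons use the Mann-Whitney rank-sum test with
midranks: exact enumeration of all C(n+m, n) arrangements when
n + m ≤ 12 without ties, otherwise a normal approximation with tie and
continuity corrections.  Both are validated against literal enumeration
oracles and against scipy's independent implementation in the tests;
under the null the permutation test rejects at 4–6% at α = 0.05 over
2000 simulated cohorts.

Dynamicity uses the sample (n−1) SD throughout (series are short);
missing frames are excluded from statistics but reported in `n_valid`.
The four behavior categories are scripted by the generator, never
classified automatically — classification was qualitative in the
motivating workflow and is out of scope.

## Division geometry

The rounded apical surface is modeled as a circular segment with chord c
(the contracted planar extent) and sagitta h: R = (c² + 4h²)/(8h),
arc = 2R·asin(c/2R), extended to the major arc when h > c/2 so arc
length is strictly increasing in h.  The flat-state path is the straight
border-to-border chord ℓ, per the assumption that the axon is anchored
at the cell borders and runs straight across the cell surface.  The
round and flat frames are the consecutive pair with the largest
border-to-border length increase (ties → earliest), which in scripted
scenarios recovers the contraction→rebound transition exactly.  Pearling
over a span is the sample SD of calibers at 1-μm increments; for a
sinusoidal diameter modulation of amplitude a it converges to a/√2.

## Numerical choices and degenerate inputs

- Tangents by central differences on polyline vertices (one-sided at
  ends); degenerate (zero-length) segments raise.
- Parabolic refinement is clipped to ±half a sample step and skipped at
  profile edges or non-concave stencils.
- Branch-role ties (S1 = S2) resolve deterministically to the lower
  segment id; symmetry is 1 either way.
- Regression r² is 0 by convention for constant response; constant
  predictors raise.
- Flat intensity profiles (zero range) raise rather than report a
  spurious caliber.
- Frame selection with monotone non-increasing border lengths raises (no
  flattening captured).
- Seeds: every stochastic path takes a single integer seed;
  per-frame noise streams are spawned from it, and reruns are
  byte-identical (asserted down to the output files).

## Problem sizes

Tests and the acceptance script run on scenes of 160–300 × 360–640
pixels (6–26 μm fields), 4–10 frame time-lapses, diameter sweeps of six
calibers × 9 positions, 100-scenario frame-selection sweeps, and a
2000-cohort null calibration with 20 pairs each; these sizes make the
whole suite run in well under a minute while leaving every statistic's
sampling error far below the asserted tolerances.

## Known limitations

- Caliber is an in-plane diameter; no correction for axons tilted out of
  the imaging plane.
- The two-line-source membrane model ignores lumen fluorescence and
  intensity variation along the membrane; amplitude is constant per
  scene.
- Sub-pixel accuracy degrades as d approaches 2σ from above, where the
  peaks pull toward each other; the resolution flag covers only d below
  the limit, so calibers slightly above it carry a small negative bias.
- The exclusion rules implement fixed thresholds (3/5 μm spacing, 20%
  below-resolution); they are configurable but not data-driven.
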