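# Methods

This note records the models, conventions and numerical choices behind
`rootph`, the reasoning where the design was genuinely open, and what
the synthetic tests do and do not demonstrate about real data.

## Measurement model

The reporter is a membrane-impermeant fluorescein-sulfonate dye
dissolved in the growth medium.  It is excited sequentially at 488 and
405 nm with a shared emission band; the excitation ratio
F488/405 increases monotonically with pH over roughly pH 4–7.  Because
the root excludes the dye, the image is a bright medium with a dark
root, and the measurable quantity is the pH of the medium at and near
the root surface (the rhizosphere), not the cell-wall pH proper.

Per-channel intensity at a medium pixel is modeled as
gain · f(pH) · L(x, y) + background, where L is a smooth illumination
field shared by both channels.  Taking the ratio cancels gain, local
dye concentration, medium thickness and L; the constant backgrounds are
subtracted beforehand (defaults 0; the instrument's flat-field
correction is assumed to have been applied at acquisition, and a
pseudo-flat-field normalization protects segmentation when it was not).

## Geometry conventions

* Coordinates are (y, x), pixel centers at integers, y increasing
  downward; the default gravity vector is +y.
* The root mask is the largest connected dark component of the summed
  channels after Otsu thresholding with intermeans (isodata)
  refinement, morphological closing (radius 2 px), hole filling and a
  minimum-area filter.  The intermeans step matters: histogram Otsu
  returns the first index of a between-cluster plateau, which for a
  noise-free bimodal image can cut inside the dark cluster.
* "Distance off the root surface" is the exact Euclidean distance
  transform of the mask complement — not a chamfer approximation and
  not a smoothed contour.  The sampling band is 10 ≤ d ≤ 25 px.
* The longitudinal coordinate s is arc length along the *midline*
  (skeleton pruned to its longest geodesic path), not along the
  contour, which would double-count the flanks and inflate with
  curvature.  Two corrections are applied: the ordered skeleton path is
  smoothed with a 9-point moving average (a raw staircase path
  overestimates curved lengths by several percent), and the midline is
  extended from the skeleton's free endpoint along the tip tangent to
  the mask boundary, because skeletons terminate about one radius short
  of the anatomical tip.  With both, rectangle and quarter-circle masks
  recover their analytic lengths within 5 %.
* The tip is the midline endpoint far from any image border (the root
  enters the field shootward); when both endpoints are comparably far,
  the endpoint with the larger projection on gravity wins.  The tip
  tangent is the principal direction of the 25 midline points nearest
  the tip.  Tip angles are unsigned angles to the gravity vector in
  [0°, 180°].
* Side labels (left/right) come from the sign of the cross product of
  the local midline tangent with the midline-to-pixel vector;
  lower/upper flanks are obtained at analysis time by projecting the
  same displacement on the gravity vector, so one code path serves
  vertical and gravistimulated sessions.

## Profile statistics

Bins are 20 px long along the midline and span the full 15 px radial
band (half-open intervals [k·L, (k+1)·L) in s).  The bin statistic is
Σ I488 / Σ I405 — the ratio of sums, not the mean of per-pixel ratios,
which is noise-amplifying and biased at low 405 counts.  Bins with
fewer than 30 pixels (the band narrows at the very tip) or a vanishing
405 sum are flagged invalid and excluded from statistics.  Profiles are
truncated at 1000 µm from the tip.  The pooled ("both") profile uses
the union of sides; per-side profiles are always available.

Calibration is applied to *bin* ratios; calibrated pH values are never
re-averaged across bins, because the monotone map does not commute with
averaging.  The default calibration model is a monotone piecewise-cubic
(PCHIP) interpolant — the inverse is computed by root-finding on the
forward spline, so round trips are exact to 1e-6 — with a 4-parameter
logistic alternative for noisy standards (fluorescein-family dyes
follow a single-pKa titration).  Out-of-range queries clamp to the
boundary and are flagged; no extrapolation, since the dye saturates.
Curves are per-session and per-medium; the CLI emits a pH column only
when a standards file is supplied.  Absolute-pH reporting is
deliberately discouraged in favor of relative comparisons against
internal controls imaged on the same medium.

## Kinetics

Frames are segmented independently; tip identity is kept by a
nearest-neighbor guard (a jump > 100 µm flags the frame).  Up to two
consecutive failed frames are tolerated and scalar series interpolate
over them; more raise a tracking-lost error.  The elongation rate is
the midline-length increment between the first and last valid frames
divided by the elapsed minutes; because the shootward end of the
midline is pinned to the field border, constant skeletonization biases
cancel in the difference.  A length decrease beyond 5 % of the initial
length raises a registration warning.

Flank series report Σ488/Σ405 per flank inside a longitudinal window,
default 200–500 µm from the tip.  That window is the package's own
choice for "the transition zone" — it matches where the alkaline domain
sits in the default profiles — and is configurable and echoed into
output metadata.  Asymmetry onset is the first time lower/upper exceeds
1 + 3·SD for two consecutive frames, with the SD taken from the first
three frames and floored at 0.002 so that noise-free series cannot
trigger on rounding error.  Oscillation analysis needs ≥ 64
fixed-interval frames: windowed mean ratio, linear detrend, periodogram
peak (period and amplitude), plus a left/right asymmetry trace.

## Group statistics

Each longitudinal bin of each root is one independent data point.  Two
groups are compared per position with the Brunner–Munzel test; the
reported effect is the midrank estimate of P(X < Y) + ½P(X = Y).
Zero-variance degeneracies are resolved explicitly: all values tied
gives (effect 0.5, p = 1); complete separation gives p = 0.  Following
common practice for these profile figures, no across-position
multiplicity correction is applied by default (per-position significance
bars); Holm adjustment is available by flag, and many-to-one comparisons
Holm-adjust across groups at each position.  All settings are echoed
into output headers.  Profiles are aligned by linear interpolation onto
the first group's bin centers restricted to the common range; invalid
bins propagate as missing.

The alkalinization factor is defined here as the per-position ratio of
group-mean profiles (treated/control) with a seeded bootstrap CI over
roots.  A difference-of-calibrated-pH variant can be obtained by
passing `column="pH"`; the choice is recorded in the output.

The alkaline-domain descriptor uses a baseline interpolated between the
profile minima flanking the search window, evaluated on a lightly
(3-bin) smoothed profile — the minimum of raw noisy bins is biased low,
which would let pure noise clear the detection threshold.  A domain is
reported when the baseline-subtracted peak exceeds 3× a robust noise SD
(successive-difference MAD of the raw profile); FWHM comes from
interpolated half-maximum crossings, and descriptors whose peak or
half-maximum extent touches the window edge are flagged
boundary-limited rather than silently truncated.

Penetration efficiency: per replicate, each genotype × pore-size
variant is normalized to the reference variant's raw efficiency in that
replicate; the reference variant itself is normalized to its
across-replicate mean (so its mean is 1 by construction, and its SD
reports between-replicate spread).  Replicates with zero reference
efficiency are excluded with a warning.

## Synthetic phantoms

The generator emulates the acquisition end to end: a tapered-radius
root along a programmable centerline (straight, tilted, or bending
about an elongation-zone pivot at a fixed rate); a longitudinal surface
pH field composed of a baseline, a Gaussian alkaline halo (defaults:
center 350 µm, σ 60 µm, +0.5 pH on a 5.2 baseline in 5.7 medium), an
acidic tip dip, an optional windowed "treatment" offset, an optional
lower-flank offset with a programmed onset, and an optional sinusoidal
modulation of the halo amplitude.  The surface pH holds through a
radial plateau of 30 px (covering the 10–25 px band) and decays
exponentially beyond it, so the band reports the programmed pH(s)
exactly; per-channel intensities follow the forward logistic optics
(midpoint pKa 6.4, ratio spanning ~4× over pH 4.5–6.0 — a test fixture,
not a claim about dye chemistry), multiplied by an optional 0.5–1.5×
illumination ramp.  Poisson noise is applied to the pre-read counts
(medium ≈ 400 counts in the 405 channel) and Gaussian read noise
(SD 2) after, matching an sCMOS qualitatively.  A single integer seed
makes stacks bit-reproducible.

What the phantoms do **not** emulate — and hence what passing tests do
not show about real data: optical blur and depth sectioning, root
hairs and lateral roots, dye-concentration gradients, medium
autofluorescence, focus drift, cation sensitivity of the dye, and
biological root-to-root variability beyond shot noise (group-comparison
phantoms differ only by noise and programmed offsets, which makes the
rank tests *more* sensitive than they would be on real populations).
Real pipelines should also expect segmentation to need parameter tuning
for low-contrast staining.

## Problem sizes and numerical notes

Default phantom frames are 768 × 256 px at 1 µm/px (kinematics examples
use 0.65 µm/px to exercise unit handling); gravitropic series use
21 frames at 2 min, oscillation series 96 frames at 5 s, group
comparisons 10 roots per group, the rank-test null calibration 10,000
simulations, and bootstrap CIs 1000 resamples — sizes chosen so the
whole suite and the acceptance script each complete in about a minute
on one CPU while leaving every tolerance comfortably resolved.
Distance and bin intervals are half-open; bin centers are reported.
Sums, not means, are accumulated per bin, so results are independent of
pixel iteration order up to floating-point summation order (~1e-15
relative).  The intermeans threshold iteration runs to a 1e-9 fixed
point (at most 20 steps).  All stochastic steps (noise, bootstrap,
simulations) take explicit seeds; the CLI generates, logs and records a
seed in the run manifest when none is given.

## Known limitations

* Single root per field, single focal plane; no multi-root scenes.
* The tip-angle estimator is a transparent tangent fit, adequate for
  phantom-validated rates but not a replacement for dedicated
  root-tracking tools on difficult real images.
* The elongation anchor assumes the root enters the field at a border
  and stays there; fields where the whole root floats lose the fixed
  anchor and the rate becomes curvature-sensitive.
* Brunner–Munzel p-values use the t-approximation; at n < 10 per group
  it runs slightly liberal, which is why preconditions require n ≥ 5
  and the type-I calibration is checked at n = 20.
* Calibration curves must not be reused across media or sessions.
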