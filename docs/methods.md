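# Methods

`oculomap` implements the statistical machinery of a gaze-contingent
face-recognition experiment in which two observer groups view face
stimuli through a "spotlight" — a Gaussian-transparency aperture of 2°,
5° or 8° diameter centred on the current fixation — while their eye
movements are recorded at 1000 Hz.  Because no human recordings are
deposited, a synthetic-data generator reproduces the structure of such
an experiment and serves as the test bed for every stage.

## Event parsing

A sample is saccadic when its angular velocity exceeds 30 °/s **or**
its angular acceleration exceeds 4000 °/s² (the OR combination is the
convention of the commercial parser these thresholds come from).
Velocity is the symmetric finite difference of position over the two
neighbouring samples, divided by the calibration factor (default
25 px/°); acceleration is the symmetric difference of velocity;
endpoints use one-sided differences.  No temporal filtering is applied
by default — the reference parser's internal filter is proprietary, so
the reproducible choice is the bare finite difference, with an optional
boxcar (`ParserSpec.smooth_window`) for borderline cases.  Kinematics
at samples within one sample of missing pupil data are undefined and
never saccade-flagged.

Blinks are runs of ≥ 3 consecutive missing-pupil samples, extended
through contiguous saccade-detector activity.  Saccades separated by
< 20 ms **and** < 0.30° are merged iteratively to a fixpoint.
Everything else is fixation.  Events tile the recording exactly
(`n_samples × dt`), so event durations always sum to the recorded span;
fixation centroids are the mean sample position (equal weights equal
duration weighting at uniform sampling).

## Aperture model

The aperture's opacity ramp is a normalised Gaussian,
`alpha(r) = (1 − exp(−r²/2σ_a²)) / (1 − exp(−R²/2σ_a²))`, with
`σ_a = sigma_frac · R` (default 0.5).  The normalisation enforces the
two constraints the display obeyed — fully transparent at the gaze
centre, fully opaque at the aperture border — for any shape parameter;
whether the original ramp was truncated or renormalised is not
recoverable, so only these boundary conditions are guaranteed.
Landmark visibility uses a transmission threshold: a landmark is
visible when ≥ 90% of its disc retains transmission above `tau`
(default 0.1, i.e. at least 10% of stimulus contrast).  A mid-ramp
`tau` of 0.5 would classify every extrafoveal landmark as invisible at
any aperture, because the Gaussian ramp passes 0.5 opacity well inside
the border; 0.1 reproduces the three qualitative relations that define
the paradigm: a fixated eye is fully visible at 2°, nothing but the
nose is visible from the nose at 5°, and both eyes and the mouth
become available from the nose only at 8°.  The default landmark
layout on the 382 × 390 px grid (eyes (142, 162)/(240, 162) r 15, nose
(191, 215) r 16, mouth (191, 285) r 18) was chosen so those relations
hold exactly; it is an artifact default, not a measured geometry.

## Fixation maps and Z-scoring

Each fixation deposits its duration (ms) at the pixel nearest its
centroid — nearest-pixel rather than bilinear splatting keeps map mass
integral and exactly equal to total fixation time.  Maps are smoothed
with a unit-sum Gaussian kernel, σ = 10 px, zero-padded at the
borders (interior mass is conserved; mass within ~3σ of the border is
attenuated — fixations live in the face interior, so this is
inconsequential).  Observer maps are summed within groups.

Group maps are Z-scored against the **pooled** pixel moments of both
groups, the operationalisation of the null hypothesis that both groups
share one fixation distribution; using a common (μ, s) keeps the two
Z-maps, and observer-level Z-maps derived with the same moments,
directly comparable.

The differential map is the difference of the two pooled-Z-scored
group maps, `z_a − z_b = (a − b)/s_pooled`.  The alternative of
re-standardising the raw difference to mean 0/SD 1 over its own pixels
is provided (`restandardize=True`) but is *not* the default, for a
structural reason: that variant is scale-free — its maximum depends
only on the spatial shape of the fixation density, not on how much
data went in — so two finite cohorts with identical strategies exceed
any fixed threshold almost surely (simulated null cohorts give
max|z| ≈ 8–11).  With the pooled denominator the differential map is
measured on the structure scale of the group maps themselves:
sampling noise between same-strategy cohorts stays near max|z| ≈ 0.3
while genuine strategy differences are structure-sized, which is what
makes the subsequent familywise threshold meaningful.

## The Pixel test

The familywise threshold z_crit solves `E[EC](t) = α` (one-tailed) or
`α/2` (two-tailed), where the expected Euler characteristic of the
excursion set of a smooth stationary Gaussian field uses the full
2D + 1D + 0D resel expansion:

    E[EC](t) = R0 (1 − Φ(t)) + R1 √(4 ln 2)/(2π) e^{−t²/2}
             + R2 (4 ln 2)/(2π)^{3/2} t e^{−t²/2}

with R2 = area/FWHM², R1 = half-perimeter/FWHM, R0 the Euler
characteristic of the search region, and FWHM = 2√(2 ln 2) σ taken
from the applied smoothing kernel (σ = 10 px) rather than estimated
from residuals.  For the full 382 × 390 map this yields
z_crit = 4.2509 two-tailed at α = 0.05, matching the threshold the
analysis is built around to the printed precision.  The corresponding
one-tailed solve gives 4.075, **not** the 4.64 sometimes quoted for
the same geometry; no (area, FWHM) convention consistent with the
two-tailed 4.25 reproduces 4.64, so the one-tailed figure is treated
as non-reproducible and both tails/alpha are exposed so either
convention can be run.  Monte-Carlo calibration (2000 white-noise
fields smoothed at σ = 10 with periodic boundaries — the stationary
construction — then Z-scored) gives an empirical familywise error of
≈ 0.03–0.05 at the computed threshold.

Suprathreshold pixels are grouped into 8-connected clusters, with the
sign recorded per cluster; an empty cluster set is a legitimate
outcome.

## ROI statistics

Each observer's pooled-normalised Z-map is averaged (unweighted pixel
mean) over each significant cluster, giving a balanced observers ×
regions table.  The two-way mixed ANOVA (region within subjects,
group between subjects) is computed by `pingouin.mixed_anova`; with
two groups of 10 and two regions the interaction has df (1, 18), and
partial η² = SS_interaction/(SS_interaction + SS_error).  The table
with all scores identical is a 0/0 degeneracy reported as F = 0.
Per-region group differences use classical equal-variance independent
t-tests (a Welch switch is provided) and Cohen's d with the pooled-SD
(n_a + n_b − 2) convention.

## Time courses

An observer's ROI frequency curve is, at each grid time, the
proportion of that observer's trials whose current fixation centroid
lies inside the ROI (saccades, blinks and post-response times count as
outside; a switch inverts this), optionally divided by ROI area.
Learning trials use an absolute 10 ms grid over the 10 s exposure;
recognition trials are first normalised to a 0–100% grid by each
trial's response time (sample-level grids are supported by the same
code; the bins keep runtimes desk-scale).  Group inference is a
percentile bootstrap: observers are resampled with replacement
independently per group B = 5000 times, and a time point is flagged
when the (2.5, 97.5) percentile interval of the bootstrapped mean
difference excludes zero.  Flags are pointwise, with no multiplicity
correction — matching the per-time-point asterisk convention of group
time-course plots.  Calibration note: with Gaussian observer curves
the interval covers the true difference ≈ 94.5% of the time at 40
observers per group; at 10 per group the percentile bootstrap shows
its usual small-sample undercoverage (~92%).

## Image statistics

Per face set, the pixelwise mean and population SD (n denominator) of
gray levels 1–256 are computed; the SD image is the information that
distinguishes exemplars.  The difference of two sets' SD images is
Z-scored over pixels and thresholded with the same Pixel test.  The SD
fields are not smoothed; the σ = 10 smoothness parameter is an
*assumption* about the spatial scale of image variation, recorded in
the output metadata.  The synthetic face generator makes this
assumption true by construction (its identity variation has an 18 px
correlation scale).

## Synthetic data

Faces are a gray background, a face oval, darker Gaussian landmark
patches, and per-identity variation consisting of a spatially smooth
random field (SD 10 gray levels, correlation 18 px, periodic
smoothing so the field is stationary to the border) plus very mild
landmark amplitude/position jitter.  The broad field dominating the
identity variance mirrors aligned, luminance-normalised photograph
sets, in which exemplar variance spreads over the whole image instead
of piling onto single features — and hence reproduces the null outcome
of the pixel-SD comparison between same-distribution sets.

Scanpaths alternate fixations and saccades.  Fixation targets are
drawn from a landmark mixture — the eye-biased profile uses weights
.35/.35 (eyes), .20 (mouth), .10 (nose); the nose-centred profile
.10/.10/.20/.60 — with isotropic Gaussian scatter of 0.5°.  Fixation
durations are Gamma(4, 77.5) ms truncated at 60 ms (mean ≈ 310 ms),
giving ≈ 29 fixations per 10 s learning trial, the scale reported for
this paradigm.  Saccade durations follow the main-sequence default
2.2·amplitude + 21 ms, shortened for small saccades so the
minimum-jerk peak velocity (1.875 A/d) stays ≥ 100 °/s, i.e. at least
three times the detector threshold.  Blinks (0.1/s) interrupt a
fixation and resume it in place.  Trials never end mid-saccade.

Sample synthesis renders fixations with slow oculomotor drift — white
noise low-passed at ~20 ms with marginal SD `noise_deg` (default
0.05°) — rather than per-sample white jitter: white jitter at 1000 Hz
has finite-difference velocity and acceleration far above both
detector thresholds and corresponds to no physical eye movement,
whereas drift-like noise matches real tracker output and keeps the
generator/parser round trip exact.  Saccades follow minimum-jerk
trajectories; blinks hold position with the pupil channel missing.

Whole experiments follow the published design: blocks of 14 learned
identities shown 10 s each, then 28 recognition trials (14 old + 14
new), two blocks per face race, 10 observers per group per aperture.
Behaviour is generated, not modelled: accuracy is Bernoulli with
default {2°: .50, 5°: .75, 8°: .90} (chance at 2° for the two-choice
familiarity decision, rising with aperture; the intermediate values
are artifact defaults shaped only by the qualitative monotone claim)
and response times are lognormal with scale decreasing in aperture.
Profiles are stationary within a trial; the within-trial shift from
locating to exploiting regions of interest is not parameterised.

### What the generator does and does not establish

Passing tests show the pipeline recovers planted strategy differences
and stays calibrated when there are none, under idealised conditions:
stationary profiles, identical observers within a group, drift-only
fixational noise, and landmark-mixture scanpaths.  Real data add
observer heterogeneity, calibration error, pursuit-like movements and
non-stationary strategies that this generator deliberately omits, so
the tests validate the statistical machinery, not the empirical
conclusions one would draw from human recordings.

## Problem sizes in the test and acceptance runs

Chosen as comfortable desk-scale sizes: threshold calibration uses
2000 simulated null fields; differential-map null calibration 200
replicates and bias-recovery power 100 replicates, each with 10
observers × 20 (8 in the quick suite) ten-second trials per group;
bootstrap coverage 1000 replicates at B = 2000 with 40 observers per
group; image-statistics null 200 replicates of 10-image sets.

## Known limitations

- The EC threshold assumes stationary Gaussian smoothness set by the
  nominal kernel; heavier smoothing from fixation scatter makes it
  conservative, residual non-Gaussianity at low trial counts
  anti-conservative.
- Zero-padded smoothing attenuates mass within ~3σ of the map border.
- The re-standardised differential variant flags density *shape*, not
  effect size (see above); it is retained only for comparison.
- One-tailed group-map thresholds are supported, but the historical
  4.64 value for this geometry is not reproducible from the stated
  conventions.
- Microsaccades, smooth pursuit, binocular fusion and online parsing
  are out of scope.
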