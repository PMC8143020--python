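# Methods

`visphys` implements two analysis toolchains for awake-primate visual
neurophysiology: (1) receptive-field (RF) mapping from rapidly flashed
annulus and wedge stimuli via bias-normalized reverse correlation and polar
tuning fits, with a repetition-subsampling efficiency analysis; and (2)
offline eye-tracking calibration by a third-order bivariate polynomial, with
per-session accuracy/precision metrics and four-parameter-logistic (4PL)
psychometrics for a visual-acuity task.  No recorded data ship with the
package; every analysis is exercised on synthetic data with known ground
truth.

## Stimulus geometry

The display model is a 1680x1050 monitor at 450 mm with 27.854 px/deg and a
120 Hz refresh (all configurable).  Screen coordinates are degrees of visual
angle relative to the central fixation point, x rightward, y upward; the
px/deg factor is treated as constant across the screen, with the exact
tangent model used only for the viewing-distance analysis
(`eccentricity_shift_for_depth`).  Raster images index rows downward; the
rasterizer owns the sign flip so the rest of the code reasons in one
convention.

Wedges subtend 9 deg of polar angle at 4.5 deg steps (80 wedges; every angle
covered by exactly two) and span the full radial extent of the annulus set.
Annuli are contiguous, each as wide as a wedge chord at the annulus
midpoint, which gives the recursion `w = 2 r sin(4.5 deg) / (1 - sin(4.5
deg))`; widths grow ~17% per ring, mirroring cortical magnification.  The
innermost radius defaults to 0.5 deg (configurable; the experimental value
is not published), and rings are appended until the monitor corner (35.6
deg) is covered.  Masks are binary (stimulus = 1, background = 0): for
black-on-gray stimuli the mask is the informative quantity in reverse
correlation, and the final map is rescaled anyway.  Radial and angular
intervals are half-open so coverage counts are exact.

Analyses that consume rasters run on a downscaled raster (default 1/10,
168x105 px) that preserves the visual extent; masks and per-pixel polar
coordinates are cached per catalog.

## MUA preprocessing

Raw voltage is re-referenced by subtracting the per-shank median at each
sample, band-passed 0.3-6 kHz (4th-order Butterworth), rectified, low-passed
with a 6th-order Chebyshev-II filter (50 dB stopband) and downsampled to
1 kHz.  Numerical choices: the Chebyshev-II stopband edge is 400 Hz
(anti-aliasing for the 1 kHz output; only order and attenuation are
standard, the corner is ours); all filters run forward-backward
(zero-phase) so the 0-100 ms response window is not delayed by filter group
delay; decimation keeps every k-th sample when the rate ratio is integer
and otherwise uses polyphase resampling.

Epochs span -100..+180 ms around stimulus onset (photodiode threshold
crossings with a 5 ms refractory).  Epochs whose within-epoch SD exceeds
10x the median SD across epochs are discarded per channel (strict
inequality; an epoch exactly at the boundary survives).  A channel counts
as stimulus-driven when at least three annulus and three wedge conditions
give responses significantly above the same epochs' baseline (one-sided
paired t-test, alpha = 0.01, no multiple-comparison correction); the
one-sided choice encodes "larger than baseline", and conditions with fewer
than two repetitions are skipped.

## RF estimation

Per channel, the mean response per annulus (against midpoint eccentricity)
is fitted with `b + A exp(-(e-mu)^2 / 2 sigma^2)` and the mean response per
wedge (against polar center) with the circular analogue
`b + A exp(kappa (cos(theta-mu) - 1))`.  The additive offset `b` is included
because MUA baselines are far from zero.  Fits are bounded nonlinear least
squares with deterministic initialization (location at the profile argmax /
circular mean, spread from the profile second moment, offset at the profile
minimum); `mu` stays inside the sampled range, `sigma` inside the sampled
extent and `kappa` in (0, 500].

RF size along the eccentricity axis (RFS_e) is the Gaussian FWHM
(`2 sqrt(2 ln 2) sigma`); the perpendicular extent (RFS_c) is the chord
`2 mu_e sin(FWHM_vм/2)` subtending the von Mises FWHM arc
(`2 arccos(1 - ln2/kappa)`) at the peak eccentricity; the scalar RF size is
`sqrt(RFS_e * RFS_c)`.

Fit quality flags: non-convergence; `width_saturated` (von Mises that never
falls to half maximum, kappa <= ln2/2); `width_at_bound` (Gaussian sigma
pinned at the sampled extent); `low_amplitude` (amplitude below twice the
residual RMS — a width from an amplitude indistinguishable from noise
carries no information).  Flagged fits propagate their flags into the RF
estimate and are excluded from subsampling error aggregates.

Reverse-correlation maps: each epoch's mean MUA (0-100 ms) multiplies the
presented mask; the per-class sum is divided pixel-wise by the bias image
(sum of presented masks), cancelling unequal repetition counts.  The
annulus and wedge maps are multiplied pixel-wise and min-max scaled to
[0, 1].  Scaling statistics are taken over the stimulus-covered field only
(bias > 0); pixels never covered (the disk inside the innermost annulus,
~0.1% of the screen) are fixed at 0.  Without this the uncovered pixels
anchor the minimum, and the half-max region of interest (ROI) degenerates
to the whole covered field whenever the squared baseline exceeds half the
squared peak.

## Subsampling / SNR analysis

For r = 1..9 repetitions (9 because that matched the least-sampled sites in
the motivating experiments) and 100 seeded draws per step, r presentations
per condition are drawn without replacement and the maps and fits are
recomputed.  Reported per draw: SNR in dB — `20 log10(mean inside ROI /
mean outside)`, amplitude convention, against the *full-data* ROI (pixels
above half the maximum of the all-data map; fixed per site across all
draws); the same SNR computed from the pre-stimulus window (-100..0 ms) as
a control; the Euclidean distance between the subsampled and full-data RF
centers (from the fits, converted to Cartesian degrees); and the signed
size difference (subsampled minus full-data).  Each (r, draw) pair uses an
independent `SeedSequence([seed, r, draw])` substream and is reproducible in
isolation.  A deterministic all-data draw is appended, for which both errors
are exactly zero by construction.  Per-r summary CIs are percentile
bootstrap over draws of the mean.

## Synthetic data

`simulate_rf_epochs` produces epoch-level MUA: the response-window level is
`baseline + gain * overlap` where overlap is the pixel-mean of (RF profile x
stimulus mask), normalized to 1 at the best stimulus, the RF profile being
the product of a radial Gaussian and an angular von Mises with the requested
FWHMs.  One Gaussian noise value per window per epoch (SD `noise_sd`) is
added and the trace clipped at zero — matching how the analyses average
within windows.  Defaults: baseline 10, gain 5, noise SD 1 (peak-condition
single-trial SNR of 5).  The baseline-dominated envelope is what real MUA
looks like and is what makes subsampled-map SNR grow with r: the expectation
of the product map is noise-free, so with a negligible baseline the SNR
curve would be flat in r.  Multi-site populations draw eccentricities
uniformly from 3-15 deg with FWHM = 0.75 + 0.2 x eccentricity (plus or minus 20%
jitter), the familiar linear size-eccentricity scaling; 10 repetitions per
condition mirror the motivating experiments.

What the generator deliberately does not emulate: non-Gaussian RF skirts,
response adaptation and latency jitter, correlated noise across conditions,
and Poisson-like (skewed) response noise.  One consequence: with an exactly
Gaussian ground truth the r = 1 size-error distribution is median-centred
near zero but bounded below by the full-data size and heavy-tailed above
(occasional broad fits), so its *mean* is slightly positive, whereas real
recordings show a negative mean (initial underestimation).  The plausible
real-data mechanism — full-data fits absorb broad RF skirts that single
repetitions cannot resolve — is outside this generator's model family.
Passing subsampling tests therefore demonstrate SNR growth, a flat baseline
control and exact convergence at full data, but not the underestimation
sign.

`simulate_gaze_session` warps true fixation/saccade gaze through a full
cubic polynomial (degrees to tracker units; invertibility over the screen is
verified numerically), adds white noise (default 0.3 deg expressed in raw
units) and optional slow Ornstein-Uhlenbeck drift.  Central fixations are
over-represented because every trial begins at the fixation point, exactly
as in the task.  `simulate_observer` draws conditions with the lowest
spatial frequency twice as likely as each other condition, Bernoulli
outcomes from the hit-rate 4PL, and hit RTs from the RT 4PL plus Gaussian
noise clipped to the 50-500 ms response window.

## Eye tracking

Anchors: one per calibration target, at the gaze-density mode.  Manual mode
accepts user-picked coordinates verbatim (the faithful analogue of manual
density-peak selection, whose criteria are not published); auto mode is a
documented surrogate: a robust-extent affine pre-alignment (quantile ranges,
not moments — the central fixation cluster dominates moments), 2D-histogram
peak detection, nearest-peak matching, mean-shift refinement.

Calibration: the full 10-term bivariate cubic per output dimension, raw
coordinates standardized before the basis for conditioning, solved by
minimum-norm least squares.  With the canonical nine-target 3x3 grid the
cubic terms x^3 and y^3 are exactly collinear with x and y on the grid, so
the system is rank-8 yet consistent; the minimum-norm solution interpolates
the anchors exactly.  Only affine-part collinearity (anchors on a line) is
rejected, with the condition number reported.

Session quality: calibrated samples in the central 2.5 deg square ("central
2.5 degrees" read as full width, configurable) are histogrammed at 0.05 deg;
the x and y marginal profiles are each fitted with a Gaussian (amplitude,
mean, SD — no additive offset: a fixation-count histogram has no floor, and
within the narrow window an offset term renders the SD unidentifiable).
Offsets are the fitted means, sigmas the fitted SDs; absolute offset/sigma
are the Euclidean norms of the per-axis values.  The offset-vs-sigma
correlation z-transforms both quantities within subject before pooling, so
between-subject baselines cannot masquerade as a correlation.

## Psychometrics

`f(x) = gamma + (lambda - gamma) / (1 + (x/alpha)^beta)`; `f(alpha)` is the
midpoint of the asymptotes and alpha is the acuity threshold.  For hit rates
gamma is fixed at the 12.5% chance rate of the 8-alternative task and lambda
bounded in [12.5, 100]; for RTs both asymptotes are bounded in [50, 500] ms.
Note `f(0+) = lambda`: for RTs the numerically smaller (fast) asymptote is
lambda, so "upper/lower asymptote" in magnitude terms maps to gamma/lambda
respectively.  Hit-rate denominators are hits + misses; early responses
(< 50 ms) and fixation breaks are not completed choices and are excluded
(configurable).  Condition means are weighted equally.  Hit-rate CIs are
exact Clopper-Pearson (beta quantiles); mean-RT CIs are BCa bootstrap with
10,000 replications.  Responses are classified early (< 50 ms), hit (correct
target within 50-500 ms) or miss.

## Pipelines and formats

Tabular data are CSV, models and specs JSON, arrays little-endian float32
with a JSON sidecar; times in ms, angles in degrees, screen coordinates in
degrees unless suffixed `_px`.  The two pipelines (`run_rf_pipeline`,
`run_behavior_pipeline`) are stage-wise resumable — a stage is skipped when
its artifacts already exist — and finish by atomically writing a manifest
with the config hash and per-artifact SHA-256 digests; identical config and
inputs reproduce identical digests.  The `visphys` CLI wraps the pipelines
and simulators.

## Problem sizes and tolerances

Test-suite and acceptance-script runs use the 1/10 raster; RF recovery runs
100 seeded simulations (20 reps/condition, gain/noise 5); the subsampling
suite runs 20 sites x 9 r-steps x 100 draws with 1000-replication bootstrap
CIs; the acceptance script's subsampling stage uses 8 sites x 50 draws.
Psychometric recovery uses ~5200 trials per run (~3000 hits, matching ~30
sessions of ~100 hits each) over 100 runs.  Session-quality recovery uses
10^5 samples and a 3% tolerance; calibration round-trips demand median
target error < 0.15 deg under 0.3 deg raw noise and < 1e-9 residuals for an
identity tracker.  FWHM formulas agree with numeric half-max searches to
about 1e-4 of a degree (grid-limited); rasterization and reverse correlation
agree exactly with brute-force per-pixel oracles.

## Known limitations

- The annulus response model (overlap summed over the mask) makes wider,
  more peripheral annuli catch more of the RF, biasing even noiseless
  recovered eccentricities outward by ~0.3 deg at 6 deg eccentricity; real
  neurons need not integrate this way.
- The r = 1 mean size error is not negative under this generator (see
  Synthetic data above).
- Auto anchor estimation assumes a roughly axis-aligned, monotone warp; a
  session with a strongly rotated tracker frame needs manual anchors.
- The session-quality Gaussian fits assume an approximately Gaussian central
  fixation cloud; strongly bimodal fixation patterns will be flagged only
  through fit failure.
- `select_responsive_sites` applies no multiple-comparison correction, by
  design, matching the motivating analysis.
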