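# Methods

This note documents the models and procedures implemented in `nvp`, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical decisions that matter when interpreting results.

## Vessel diametry (FWHM along skeleton perpendiculars)

The mean image of a registered movie is Otsu-thresholded; the largest
connected component is thinned to a one-pixel centreline, ordered by
nearest-neighbour walking, and per-point unit tangents are fitted as the
principal direction of a 5-point neighbourhood.  Per frame, an intensity
profile is sampled (bilinear, 0.5 px steps) perpendicular to each tangent
over ±20 µm (twice a typical maximal pial diameter — profiles must contain
baseline on both sides of the vessel), profiles are averaged over a running
window of 5 adjacent skeleton points (shared geometry, independent noise),
and the diameter is the mean FWHM of the valid profiles.  A frame with
fewer than 50% valid profiles is flagged invalid with a reason code and
excluded from averages.

**FWHM contract.**  Baseline = mean of the outer 10% of samples on each
side; half-maximum = baseline + (peak − baseline)/2; width = distance
between the two half-maximum crossings flanking the global peak.  Crossings
are localized on a cubic-spline interpolant of the profile (8× upsampled).
Linear interpolation between samples is biased by several percent when the
peak is only 1–2 samples wide; the spline keeps the error below 1% down to
a Gaussian of σ = 1 px.  The estimator is invariant to translation and to
positive rescaling of intensities.

**Degenerate inputs.**  A profile with no crossing on one side (vessel
clipped by the sampling window) or a peak at/below baseline returns NaN
rather than raising; the per-frame validity fraction handles accumulation.

## RBCV (radon velocimetry)

A kymograph window (default 128 lines, 50% overlap) is mean-subtracted,
circle-masked, and radon-transformed over angles (0°, 180°) in 0.25° steps;
the angle maximizing the variance of the projections gives the streak
slope: with rows as time and columns as space, a displacement of u px/line
appears at tan θ = u, so v = pixel_size · line_rate · tan θ (positive =
toward increasing position index).

Two refinements beyond the plain variance argmax:

- **Quality floor.**  Window variance contrast (max/median) is compared to
  the same window with its lines randomly permuted, which destroys streak
  alignment while preserving intensity statistics.  Windows below 2× that
  self-calibrated null are flagged invalid (blank, saturated, or
  streak-free windows).  Pure-noise kymographs flag 100% of windows.
- **Sub-grid slope.**  The coarse angle is refined by a shear-and-project
  sweep: each line is shifted by −u·(t − t₀) and the variance of the column
  means is maximized over a fine grid of u (the same criterion as radon at
  the exact angle, but on the full rectangular window and uniform in
  displacement).  Steep streaks (|u| > 1 px/line) are refined on the
  transposed window where they run near-vertical and every streak spans the
  window.  The projection is accumulated on a 2× oversampled column grid
  (a 1 px grid aliases ~1 px-wide streaks), and the estimate is the
  centroid of the squared above-baseline score lobe, which is robust to
  plateau noise.  Without these steps the tan θ nonlinearity turns the
  0.25° grid into ~10% velocity quantization at 5 mm/s.

At high speeds, windows that contain only a few short streak crossings can
carry too little slope information; they fail the quality floor and are
reported as flagged, not as numbers.

## Stimulus-locked trials

Traces are cut into 30 s trials: 5 s baseline, 5 s stimulus, 20 s post
(defaults follow the 5 s drifting grating / 25 s grey screen protocol,
20 presentations).  Trials whose window does not fit in the recording are
dropped with a logged reason.  A trial is excluded when locomotion speed
exceeds `speed_eps` (default 0 — any encoder motion counts) anywhere in
[onset − 2 s, onset + 5 s]; gating is idempotent.  Each retained trial is
normalized to percent change of the mean over the final 1 s of its
baseline; the responsiveness rule compares the stimulus-window peak to 2×
the SD of the full 5 s baseline of the normalized trace (normalization
window and SD window deliberately differ; both are honored as stated).
AUC is the trapezoidal integral over the stimulus window of the normalized
trace, with no drift correction.  Per-vessel responsiveness = 100 ×
responsive / retained; excluded trials never enter the denominator.  Two
aggregation surfaces exist: per-trial metrics (used for responsiveness) and
metrics of the mean retained trace (used for group response sizes and the
NVCi numerator).

The null calibration of the 2-SD rule is checked against a brute-force
Monte-Carlo simulation of the same event on white-Gaussian trials; at
7.63 Hz the null responsive rate is ≈ 60% (a max over ~38 stimulus samples
is compared with 2 SD), which is why locomotion gating and trial averaging
matter for interpretation — the rule is a within-vessel comparison, not a
familywise test.

## Vasomotion

Diameter traces (NaN frames linearly interpolated) are linearly detrended
and Welch-transformed with 1/0.01 Hz = 100 s Hann segments at 50% overlap,
giving 0.01 Hz resolution; the spectrum is interpolated onto a common
0–1 Hz grid and values above 1 Hz are discarded.  The readout is the power
at the grid point nearest 0.1 Hz divided by the total grid power ≤ 1 Hz
("relative power", unit-free across vessels).  Traces shorter than 1.5
segments (150 s) raise an error — a 0.01 Hz resolution cannot be had from
less.  The readout is invariant to offsets and linear trends, lies in
[0, 1], and changes ≤ 10% between 7 and 14 Hz samplings of the same signal.

## Net haemodynamics

CMRO2 = CBF · Hbd/Hbt elementwise; samples with Hbt ≤ 0 are flagged NaN.
Stimulus-evoked CMRO2 is computed per-sample and then trial-averaged.
Rest baselines pool all samples from locomotion-free periods ≥ 10 s (same
`speed_eps` contract as gating); pooling makes the result the
duration-weighted mean of the per-period means.  Reference-group
normalization divides each per-mouse value by the reference group's mean at
the same timepoint, per channel.  Hbt is validated against Hbo + Hbd with a
5% median-relative warning (probes drift; a hard error would be wrong).

## Neuronal calcium and NVCi

Baseline events: within each rest period, peaks are local maxima exceeding
median + k robust SD (1.4826·MAD, k = 3 default) with equal prominence and
≥ 1 s separation; rates are per-minute, duration-weighted across periods.
Stimulus classification runs on trial-averaged, baseline-subtracted dF/F:
ON = stimulus-window peak > 2× baseline SD; OFF = post-offset *rise* (peak
minus the value at offset, over a 5 s window) > the same threshold —
measuring the rise keeps a decaying ON tail from counting as OFF; BOTH =
both, NONE = neither.  NVCi = vessel stimulus AUC / mean neuronal stimulus
AUC of the vessel's group; grouping defaults to genotype (calcium data is
not always available per mouse), configurable to genotype × exercise ×
timepoint.  NVCi is linear in vessel AUC and homogeneous of degree −1 in
the neuronal AUCs, so matched vascular and neuronal amplitude changes
cancel — the property that makes it a coupling index rather than a response
size.

## Ex vivo morphometry

Candidate thresholds (IsoData/"Default", Huang, Huang2, Li — the Huang
variants are fuzzy-entropy minimizers implemented here) are computed on a
Gaussian-denoised copy and applied to the raw stack (applying to the
blurred stack dilates tubes by ~1 voxel).  The winning mask maximizes a
deterministic segmentation score, foreground connectivity ÷ surface
fraction, replacing a per-image human choice with a reproducible rule; the
choice is logged.

Centrelines are traced with a distance-field-guided geodesic path peeler
(TEASAR-family): edge weights through the foreground voxel graph are
inflated away from the Euclidean-distance-field ridge, shortest paths are
traced from a geodesic extremity to the farthest uncovered voxel, each path
voxel covers a ball of 1.5× its local radius, and tracing repeats until the
component is covered.  This is robust on anisotropic, noisy-edged tubes.
Total length is measured on branch polylines smoothed with a 5-point moving
average (raw voxel paths overestimate oblique runs by up to ~8% through
staircase steps); branch points are skeleton voxels with ≥ 3 neighbours,
counted as spatially contiguous clusters.  Radii are the anisotropy-aware
Euclidean distance transform sampled at skeleton points; length density is
reported as mm/mm³ with an optional diameter cutoff (capillaries: < 7 µm)
using per-point length shares.  Pericyte somata snap to the nearest
skeleton point within 5 µm (farther somata are excluded with a warning);
diameter-vs-soma-distance profiles bin unsigned along-skeleton path
distances (2 µm bins to 50 µm), assigning each point to its path-nearest
soma — a sign convention is not well defined on branching networks, and the
phantom profiles are symmetric by construction.

## Home-cage activity

Pose tables (frame, label, x, y, likelihood) are filtered at likelihood ≥ 1
by default — deliberately strict, keeping only perfectly confident labels;
the removed fraction is always reported so the effect is visible.  The
mouse centroid is the mean of available body-part labels (≥ 1 required),
the wheel marker the mean of its two labels; per-frame distance =
|Δcentroid| + |Δwheel|, differencing across gaps left by filtered frames.
Wheel displacement is used as measured in the camera plane, with no
rotations-to-circumference conversion.  10-minute window sums are trimmed
by floor(0.01·n) windows from each tail (tracking-failure outliers), and
daily totals / hour-of-day means use surviving windows, so enlarging the
trim can never raise a total.

## Cross-measure statistics

Exercise is z-scored across the cohort within timepoint (Pearson r is
insensitive to the affine choice).  Per measure: pairwise-complete Pearson
r with a Fisher-interval 95% CI, Fisher Z = atanh r, raw and
Benjamini–Hochberg-adjusted p-values; a one-sample t-test locates the Z
distribution against 0.  Correlations with < 3 complete pairs are flagged
and excluded from Z summaries; duplicate mouse rows are rejected.

PCA preparation: variables missing in strictly more than 20% of rows are
excluded; remaining gaps are imputed (column mean by default — 
deterministic; chained-regression imputation available behind a flag with a
fixed seed); variables are standardized and the correlation matrix
eigendecomposed (correlation, not covariance, because the measures are on
different scales); components with eigenvalue strictly > 1 are retained;
a variable's contribution to a PC is its squared loading as a fraction of
that PC's total.  Eigenvalues sum to the retained-variable count; with
complete data the result is plain standardized PCA.  Linear mixed models
and their ANOVA are not re-implemented: `tidy_observations` validates and
emits a per-observation table with the factor structure genotype ×
exercise × duration × vessel type and animal ID as the random effect, ready
for any standard mixed-model tool.

## Synthetic data: what it emulates and what it does not

Generators are bit-reproducible given a seed and cover every input format:

- **Vessel movies** — one straight bright ridge; cross-section is a box of
  the true width convolved with a Gaussian PSF (σ default 0.3 µm), so the
  true FWHM is analytically known; additive Gaussian noise; defaults
  7.63 Hz, 0.23 µm/px.  Width must exceed 2 px (resolvability guard).
- **Kymographs** — dark streaks of slope 1/velocity, Poisson-placed, with
  the dip smeared along the intra-line sweep interval (a cell moving u
  px/line traverses that span during one scan line — without this motion
  blur, fast streaks degenerate into disconnected dashes that carry almost
  no slope information); defaults 1092 Hz, 0.2 µm/px.
- **Haemodynamics / calcium** — gamma-variate transients (smooth,
  single-peaked, the standard haemodynamic response shape), peak-normalized
  so a stated amplitude is exactly the noiseless trial peak; Hbt = Hbo +
  Hbd exactly before noise; ON/OFF/BOTH cells rise at onset/offset/both.
- **Anatomy stacks** — capped-cylinder tube networks at 1 × 0.45 × 0.45 µm
  voxels with known centreline length and per-point radius; pericyte
  constrictions multiply the local radius by (1 − c·exp(−s²/2σ²)) along the
  axis.
- **Tracking tables** — body parts at fixed offsets around a centroid
  moving at constant speed along a waypoint polyline of known length; wheel
  markers rotating about a hub; dropout frames get likelihood < 1.
- **Cohort bundles** — per mouse × timepoint: schedule, locomotion bouts,
  calcium traces and per-vessel diameter traces in which each trial is
  responsive with probability 0.95 × group multiplier and responsive trials
  carry a transient of 8% × group multiplier (lognormal jitter, σ = 0.1),
  plus 0.08–0.12 Hz vasomotion (2% of diameter — a per-vessel frequency
  inside the physiological band rather than a pure 0.1 Hz tone, whose 10 s
  period would phase-lock to the 30 s trial cycle and never average out)
  and 1% white noise.  The default multiplier table plants a genotype
  deficit, an exercise benefit, a synergy making the sedentary-E4 group
  worst, and slightly enhanced neuronal responses in active E4 — measured
  full-ordering recovery probability across responsiveness, response size
  and NVCi is ≈ 97% per run at 3 mice × 6 vessels per group.  Bundles are
  emitted at the extraction level (diameter traces, dF/F, locomotion), not
  as raw movies: the movie and kymograph extraction stages are exercised by
  their own generators, and a cohort of full movies would add runtime, not
  coverage.

Passing the synthetic benchmarks shows the estimators are correct on their
stated models.  It does not certify performance on real recordings: real
two-photon noise is mixed Poisson/electronic rather than Gaussian, vessels
curve and branch within the field, motion registration is imperfect,
kymograph streaks vary in contrast with haematocrit, and real vasomotion is
broadband.  The defaults (PSF width, noise levels, streak density, effect
multipliers) are stated above precisely so that users can judge their
distance from a given preparation.

## Problem sizes

The test suite and the reproduction script run on one CPU using
deliberately small problem sizes: 40–1200-frame movies at a 128 px (64 px
for long recordings) field, 1024-line kymographs, 20-trial recordings,
300 s vasomotion traces, ~0.001 mm³ anatomy phantoms, and cohorts of 3 mice
× 6 vessels per group with 10–20 seeded replicates.  These sizes were
chosen as the smallest at which the statistical checks (ordering recovery,
null calibration, Monte-Carlo tolerances) are stable.
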