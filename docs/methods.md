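# Methods

## Video respirometry

**Model.** Respiration moves the fur on a sleeping mouse's flank; a
camera at 30 fps records that motion. The waveform's amplitude depends
on camera distance and viewing angle, but its frequency does not — the
frequency is the respiratory rate. The chain is:

1. *Seeding.* Up to 10 Shi-Tomasi corners (largest minimum eigenvalue of
   the gradient structure tensor, `skimage.feature.corner_shi_tomasi`)
   per region of interest on frame 0, separated by ≥ 7 px, strictly
   inside the ROI polygon. ROIs are user polygons or an automatic mode
   that takes the highest-temporal-variance region (respiration is the
   dominant motion in footage of a sleeping animal).
2. *Tracking.* Sparse iterative Lucas-Kanade on a 3-level Gaussian
   pyramid, 21 × 21 px windows, bilinear sampling, compiled with numba.
   A point is invalidated when its structure tensor is near-singular,
   the update diverges, the window leaves the frame, or backward
   re-tracking lands > 1 px from the starting position
   (forward-backward check). Lost points are never re-acquired: phase
   continuity of the waveform matters more than point count.
3. *Waveform.* Each track (≥ 50 % frame coverage) is projected onto its
   first principal motion direction, detrended by subtracting a 1-s
   moving average (removes posture drift), and normalized to unit SD.
   Tracks are sign-aligned to the first track (flank and shadow move in
   opposite phase) and combined by pointwise median — one incoherent
   track cannot corrupt the waveform.
4. *Rate.* Largest periodogram peak (Hann window, 8× zero-padding)
   within a physiological band, default 60–400 bpm — bracketing reported
   mouse rates (~140–190 bpm) with margin — refined by parabolic
   interpolation of the log spectrum. For a noiseless sinusoid this is
   exact to well under 0.5 bpm at any in-band rate.

**Quality control.** Manual clip screening ("no gasping, sniffing, or
pauses") is automated by two statistics: spectral peak prominence (peak
power over median in-band power, threshold ≥ 5) and the coefficient of
variation of inter-breath intervals from peaks of the band-passed
waveform (threshold ≤ 0.25). Both thresholds are configurable; the
defaults flag a 4-s pause reliably while passing jittered regular
breathing (CV ≤ 0.08). Per-mouse summaries take the median over
QC-passing clips and warn below 5 usable clips.

**Tracker parameters.** Window 21 px, 3 pyramid levels, ≤ 30 iterations
to a 10⁻³ px update, forward-backward threshold 1 px. The source
technique does not state its parameters; these follow common optical-flow
practice and are exposed on `LKParams`.

## Synthetic breathing video

The generator renders what the measurement chain needs and nothing more:
a static smooth-speckle background (dense in trackable corners, as fur
is) and an elliptical flank patch whose *texture* translates by
`amplitude_px · s(t)` along a fixed axis, inside a static patch outline.
`s(t)` is a raised cosine per breath cycle with 0.4/0.6 inhale/exhale
asymmetry — fundamental frequency exactly the breath rate, waveform not
a pure sinusoid. Inter-breath intervals are truncated-normal with the
requested CV; a whole-scene linear drift emulates slow posture change;
intensity noise is additive gaussian before 8-bit quantization. Events:
`gasp` (one cycle at 3× amplitude), `pause` (flat segment), `sniff`
(3× rate burst) — minimal parametric stand-ins for the exclusion
criteria. Frames default to 256 × 256 (desk-scale, configurable), not
1080p. Defaults: amplitude 2 px (free choice; the source states no
camera geometry), jitter CV 0.05, noise SD 0.02.

What a green test establishes: the pipeline recovers rates within 5 bpm
on ≥ 98 % of clips *of this stated world*. What it does not: robustness
to fur deformation (the patch translates rigidly), lighting changes,
occlusion, multi-animal scenes, or rates aliasing above Nyquist.

## Lung CT densitometry

Volumes are mass-density grids (g/cm³) with mm spacing, axes
(slice, row, col); Hounsfield inputs are mapped linearly through
air (−1000 HU → 0 g/cm³) and water (0 HU → 1 g/cm³) anchors. The body
mask is the largest 26-connected component above 0.9 g/cm³, hole-filled
(pulling the lungs inside). Healthy lung = density in [0, 0.7) g/cm³
(half-open: exactly-soft-tissue partial-volume voxels excluded
deterministically) ∩ body, hole-filled slice-wise, keeping the ≤ 2
largest 26-connected components (two lungs). Volume = voxel count ×
voxel volume.

The seven density ROIs (4 × 1.5 mm apex, 3 × 2.4 mm base) are anchored
at fixed *fractions* of the lung-mask bounding box: placement is
deterministic and equivariant under whole-voxel translation, which is
the property that guarantees "same positions at every timepoint". The
default fractions put each square ROI on a lung axis, clear of the
mediastinum and inside the tapering elliptical cross-section; the exact
in-lung coordinates of the original protocol are not published, so these
are this package's choice. Per-scan lung density is the unweighted mean
of the 7 ROI means.

**Phantoms.** Soft-tissue body ellipsoid (1.06 g/cm³) containing two
prolate lung ellipsoids (default 8 × 3 × 3 mm semi-axes, 0.40 g/cm³).
Injury converts the apex-side cap holding a requested volume fraction of
one lung to 0.90 g/cm³ (cap plane from inverting the ellipsoid
cap-volume cubic). Closed-form volumes make 1 %-level voxelization
accuracy checkable; at 0.1 mm spacing the segmented volume is within
0.1 % of (4/3)πabc.

## Cohort statistics

**Dichotomization.** Abnormal = beyond mean ± 3 SD of the control group
(0 Gy, both field arms pooled, n = 20) in the adverse direction
(respiratory rate ↑, lung density ↑, healthy volume ↓), at 5 months
post-irradiation, falling back to 4 months for earlier deaths. Values
exactly at the cutoff are normal ("no more than 3 SD" is inclusive).
Animals lacking both timepoints are excluded with a logged reason.

**Hill fits.** P(D) = 100 / (1 + (ED50/D)^h), bottom fixed at 0 %, top
at 100 % (responses are percentages of animals abnormal; observed
asymptotes are 0 and 100). Fitting is least squares on group-level
percentages — mirroring the plotted-curve workflow — via multi-start
Levenberg-Marquardt on (log ED50, log h). ED50 comparison is the extra
sum-of-squares F-test: null = one shared (ED50, h) for both arms;
alternative = separate (ED50, h) per arm (a share-slope variant with one
extra parameter is selectable). The alternative's starts include the
null solution, so RSS_alt ≤ RSS_null holds by construction. Dose-0
groups are excluded from fits by default: the model pins P(0) = 0 and
dichotomized controls are structurally ≈ 0 % abnormal, so they
contribute residual degrees of freedom with no error variance and
inflate the F statistic.

**Known limitation — F-test calibration at steep slopes.** At the study
design (6 positive doses, 10 animals per dose per arm) with a steep
true curve (h = 12, matching the published dose-response shape), the
edge doses sit at response probabilities ≈ 0.08 and 0.88 where 10-draw
binomial percentages are frequently exactly 0 or 100. The resulting
heteroscedastic, non-gaussian errors make the F-test anti-conservative:
measured type-I error ≈ 0.083 at nominal α = 0.05 (1000 null
replicates). The identical machinery calibrates correctly at gentler
slopes (0.052 at h = 4, 0.055 at h = 8; 400 replicates each). Users
testing very steep dose-response data should prefer simulation-based
p-values; the package reports the classical F-test because that is the
method being re-implemented. ED50 *estimates* are unaffected: the
fitted ED50 ratio at a 3 % field effect is unbiased to < 1 % across 500
simulated cohorts.

**Survival.** Kaplan–Meier and the two-group log-rank test, and Cox
proportional-hazards models (univariate and multivariate), delegate to
`lifelines` (Efron tie handling); the log-rank statistic is verified in
tests against a from-scratch risk-table computation, and Spearman's rank
correlation against a midrank Pearson formula. Time scale is days
(simulated months × 30.4375).

**Synthetic cohorts.** Doses (0, 9, 10, 10.5, 11, 12, 13) Gy, 20 animals
per dose split between 0 T and 1.5 T arms; the 1.5 T ED50 is the 0 T
value × a configurable multiplier (0.97–0.98 emulates the reported
2–3 % shifts). Each animal responds with the probability of its arm's
Hill curve at its dose (a deterministic threshold mode exists for
boundary cases); responders die at a lognormal month (median 5,
σ = 0.15, clipped to [3, 7.9]) and are events, non-responders are
censored at 8 months. Metric trajectories are control mean + a
responder shift of 6 control-SDs (adverse direction) ramping in over
months 1–4, plus truncated-normal noise clipped at ±2.9 SD. The
truncation is deliberate: responders can never fall below +3.1 SD nor
controls rise above +2.9 SD at the assessment timepoint, so generated
labels are *exactly* recoverable by the 3-SD rule — label-agreement
tests are sharp, at the cost of slightly sub-gaussian tails. Animals
dying before month 4 lack both assessment timepoints and are excluded,
as in the real workflow; this removes ≈ 7 % of responders
(dose-independently in both arms), leaving the fitted ED50 *ratio*
unbiased while absolute ED50s shift by ≈ +0.6 %.

## Numerical choices

- Rate estimation uses an 8×-zero-padded FFT with Hann window; parabolic
  interpolation on the log spectrum; ties in the in-band argmax resolve
  to the lowest bin (numpy argmax convention).
- Tracking samples images bilinearly; gradients are per-level central
  differences; the backward consistency pass starts from the known
  forward displacement and therefore uses a single pyramid level.
- Hill fitting clips log-parameters at ±50 to keep Levenberg-Marquardt
  probes finite; percentages are fitted unweighted.
- Degenerate inputs fail loudly: all-0 %/all-100 % dose-response, zero
  in-band spectral power, empty lung masks, zero-variance Cox
  predictors, and constant Spearman inputs raise or flag rather than
  returning silent numbers.

## Reproducibility

Every stochastic routine takes an explicit integer seed
(`numpy.random.default_rng`); identical configs give bit-identical
frames, phantoms and cohorts. `vivorate.pipelines.run` validates configs
strictly (unknown keys rejected), stages outputs atomically, and writes
a manifest (config hash, package version, timestamp) beside results.
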