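# Methods

## Scope and data model

`ccopheno` phenotypes chambered cardiac organoids from two recording
modalities: brightfield time-lapse video (a `FrameStack`: ordered grayscale
frames at a fixed interval; timestamps are `index × frame_interval`, never
container metadata) and single-channel fluorescence traces (`CalciumTrace`:
intensity on a uniform time grid). Areas are reported in px² and thickness in
px; no physical calibration is applied unless the user converts downstream.
Image coordinates are row-major with the origin top-left; color input is
collapsed to grayscale by unweighted channel mean (brightfield/monochrome
sources dominate, so no luminance weighting is warranted).

## Segmentation

Each frame passes through: Gaussian smoothing (σ = 2 px by default) →
automatic Otsu organoid/background threshold → largest connected component
(ties broken by lowest centroid row, then column), hole-filled → the outer
mask. A second Otsu threshold over the organoid interior separates the
bright chamber ("hollow core of a lighter shade") from the darker wall; the
largest component strictly inside the outer mask becomes the inner mask. A
config flag inverts the chamber polarity for recordings with the opposite
contrast. Components below `min_object_px` (64) are discarded.

Two guards matter in practice:

- **Interior margin.** Smoothing widens the organoid/background edge into a
  ring of intermediate intensities; interior statistics therefore exclude a
  margin of `⌈3σ⌉` px inside the outer boundary, otherwise the ring
  masquerades as a second intensity class and a solid organoid grows a fake
  chamber.
- **Contrast gate.** The interior split is only accepted when the
  chamber/wall contrast exceeds `rel_chamber_contrast` (default 0.2) of the
  organoid/background contrast; below that the organoid is reported solid
  (inner area 0). This keeps noise from being segmented into a chamber.

After the first pass, thresholds are refined once to the midpoint of the
adjacent class means (background/wall): for a symmetric blur the true
boundary sits at the half-way intensity, which Otsu misses when class sizes
are unbalanced. On rendered annuli this brings area errors from ~1.5 % to
≲ 0.1 %.

Wall thickness defaults to the **equivalent-circle** definition
`√(A_out/π) − √(A_in/π)` — robust to irregular outlines and consistent with
the area-based metrics. A distance-transform variant (4× the mean wall-
interior distance to the nearest non-wall pixel, exact for a straight band)
is available for sensitivity analysis.

Frames that fail segmentation (blank/degenerate) are flagged and linearly
interpolated from neighbours when they are fewer than 5 % of the stack;
otherwise the whole recording is rejected with a per-frame report. Failures
never silently become zeros.

## Contraction kinetics

The outer-area trace is smoothed with a 3-frame centred moving average and
beats are found at the negative-to-positive zero crossings of the first
difference — local area minima, i.e. peak systole — subject to a prominence
of at least 0.2× the trace range and a minimum spacing of 0.2 s. Each
systole is paired with the preceding area maximum (diastole). Choosing
minima vs maxima does not affect interval statistics for periodic traces;
the convention is recorded in outputs. Interval statistics use the sample SD
(n−1). Undefined metrics (fewer than two beats) are explicit NaN.

Fractional shortening is, per beat, the percentage change of wall thickness
between the paired diastole and systole; it is positive when the wall
thickens during contraction. An echocardiography-style chamber-diameter
convention (relative reduction of the inner equivalent diameter) is
available via config. Both the per-beat values and their mean are reported;
frequency is emitted both per minute and per second. Week-over-week wall
thickness is normalized per organoid to its week-0 value; organoids lacking
a week-0 record are excluded with a warning.

## Calcium kinetics

Analysis restricts to the first 30 s of a recording by default (recordings
are nominally 1 min). Baseline is a rolling low-percentile (10th percentile
over a 10 s window, edge-padded; the window should be ≥ 5× a typical
transient). Peak detection and baseline estimation run on a lightly smoothed
copy (3-sample moving average) because raw-trace noise peaks can reach
prominences of several σ and forge events; the per-event metrics are then
measured on the raw trace, whose steep crossings are less biased by
smoothing. Onset/end thresholds sit at 10 % of the peak amplitude (so CTD is
effectively a CTD90); both fractions are configurable and stamped into
outputs. Repolarization-x times are linearly interpolated between samples.
Decays truncated by the trace end (or masked by the next transient before
reaching the threshold) yield NaN, never fabricated values.

Depolarization speed is amplitude divided by upstroke duration — the mean
rate of fluorescence *rise*. The variable is sometimes verbally described as
a fluorescence decrease per second; for an upstroke measure that direction
is contradictory, and this package deliberately reports the rise rate.
Peak intensity is baseline-subtracted.

## Cohort statistics

Two-sided throughout; no multiple-testing correction. The policy routes to
the Mann–Whitney U test when either group has fewer than `small_n_cutoff`
(default 8) samples — exact null distribution when there are no ties, normal
approximation otherwise — and to Welch's unequal-variance t test for larger
groups. Student's t is available by explicit request (qPCR- and
calcium-style comparisons). Each result records which test ran, the group
sizes, and a star annotation at the 0.05/0.01/0.001/0.0001 thresholds.

## Single-cell QC

Cells are retained with 2000–7500 detected features (inclusive bounds, read
as a closed band) and a mitochondrial read fraction strictly below 10 %;
genes are then retained when expressed (count > 0) in at least 10 of the
*retained* cells. The order matters and is fixed: cell filter first, gene
filter second (a gene expressed in 10 cells of which one fails cell QC is
dropped). Mitochondrial genes are recognized by the human `MT-` prefix,
case-insensitively. MatrixMarket triplets are read plain or gzipped, and a
transposed matrix is auto-corrected from the name counts.

## Synthetic generator: what it emulates, and what it does not

The generator renders a **concentric annulus** — bright chamber core, darker
wall, dark background — because the analytic areas `πR²` give exact oracles.
Within each beat cycle the inner radius falls along a half-cosine over
`contraction_rise_fraction` (default 0.35) of the cycle and recovers along a
half-cosine over the rest, so contraction is faster than relaxation; a
fraction `outer_coupling` (default 0.5) of the excursion is transmitted to
the outer radius, making the wall thicker at systole. Beat intervals are
drawn from a normal distribution truncated below at 0.2× the mean to prevent
cycle overlap; only complete cycles are animated, so every programmed
systole is observable in the frames. Ground truth (systole times, radii,
fractional shortening, interval statistics) follows from the programmed
waveform in closed form.

Default study conditions: 192 px frames, outer/inner diastolic radii
70/35 px, pulsation fraction 0.15 (programmed FS 7.5 %), ~1 Hz rhythm with
50 ms interval SD, 30 s at 10 frames/s (~300 frames per recording),
intensities 200/120/40 with pixel noise σ = 4 (5 % of the wall/background
contrast). Calcium traces use the two-exponential kinetic
`(1 − e^(−t/τ_up))·e^(−t/τ_down)` with τ_up = 80 ms, τ_down = 250 ms,
amplitude 80 a.u. over a baseline of 100 a.u., 1 min at 50 Hz, noise
σ = 2 a.u.; repolarization truths are root-found on the noiseless waveform
to 1e−12 (for τ_up → 0 they reduce to τ·ln(1/(1−x))). Toy count matrices
program detected-feature counts exactly and mitochondrial fractions to count
rounding, with the 13 human mitochondrial protein-coding gene names.

Not emulated: irregular organoid outlines (an optional low-order harmonic
boundary perturbation exists for robustness tests only), texture, focus
drift, motion blur, multi-organoid fields, photobleaching beyond a linear
drift term, and transient-shape heterogeneity. Passing tests therefore
demonstrate the correctness of the measurement definitions and the
detector's noise robustness at realistic SNR — not performance on irregular
morphologies, which the segmentation handles only insofar as its
area-based definitions are shape-agnostic.

Cohorts expand one seed into per-organoid sub-seeds by a fixed affine
increment, so each organoid is individually reproducible and keeps its
sub-seed across weeks (a week-over-week change reflects only the programmed
effect multipliers). Effect multipliers act on diastolic wall thickness (by
shrinking the inner radius), beat rate (dividing the interval mean),
interval SD and pulsation fraction.

## Numerical choices and degenerate inputs

- Constant traces yield zero beats/transients (valid empty results), not
  errors; blank frames are segmentation failures (flagged), and an all-blank
  stack is a quality error.
- Uniform-grid checks: traces to 1e−9 relative, beat detection to 1e−6.
- A beat-interval measurement floor exists at the frame interval (0.1 s
  video sampling quantizes systole times, inflating small interval SDs);
  with a programmed SD of 0.1 s the recovered SD is accurate to ~10–20 %.
- Fractional-shortening means at default conditions recover programmed
  truth to well under 1 percentage point (noiseless and at 5 % pixel noise).
- `extract_frames` picks the native frame nearest each requested timestamp
  and yields exactly `⌊duration/interval⌋` frames.
- Problem sizes in the test-suite and the acceptance script (30–40 s videos
  at 192–256 px, 1000-replicate type-I simulations at the metric level) were
  chosen so the full validation runs in minutes on a single CPU while
  keeping ≥ 30 beats/transients where interval statistics are asserted.

## Known limitations

- The segmentation is single-organoid-per-field and assumes the chamber is
  resolvable as a second intensity class; no tracking, registration or
  drift correction.
- Equivalence with any specific CellProfiler pipeline configuration cannot
  be asserted; only the downstream metric definitions are fixed.
- The exact-test variant (tie handling, continuity correction) follows
  scipy's `mannwhitneyu`; other software may differ in the tied case.
- Train-measured CTD/repol90 sit slightly below isolated-transient truth at
  ~1 Hz rhythms because consecutive transients overlap (fusion); this is a
  property of the signal, not a detector artefact.
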