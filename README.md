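# ccopheno

Computational phenotyping of **chambered cardiac organoids (CCOs)** —
self-organized 3D cardiomyocyte aggregates with a central chamber whose wall
contracts spontaneously. From brightfield time-lapse video and GCaMP
fluorescence recordings, `ccopheno` quantifies the structural and functional
phenotypes used to detect drug-induced hypertrophy in vitro: chamber wall
thickening, contraction rate and rhythm variability, fractional shortening,
and calcium-transient kinetics. A single-cell QC module covers the standard
count-matrix filtering step, and a two-group statistics module applies the
small-sample comparison policy used for organoid cohorts.

Because real organoid videos are large and rarely shareable, the package
ships a fully ground-truthed **synthetic-data generator**: a pulsating
annulus with programmable geometry, beat statistics and pixel noise whose
analytic areas (`πR²`) give exact oracles for the segmentation stage, plus
calcium-transient trains and toy count matrices with programmed violations.
Every downstream stage is validated against these known answers.

## The measurements

Per frame, the organoid is segmented into an outer (whole-organoid) mask and
an inner (chamber) mask; with `A_out` and `A_in` the mask areas in px²:

- wall area `A_wall = A_out − A_in`, wall fraction `A_wall / A_out`;
- equivalent-circle **wall thickness** `T = √(A_out/π) − √(A_in/π)`;
- beats are located on the outer-area trace as the extrema bracketed by sign
  changes of the first-order difference: peak **systole** = area minimum,
  paired with the preceding maximum (**diastole**); contraction frequency is
  `60 / mean(interval)` beats/min and rhythm variability the sample SD of the
  systole-to-systole intervals;
- **fractional shortening** per beat: `FS = 100·(T_sys − T_dia)/T_dia` (%),
  positive when the wall thickens at systole;
- per calcium transient: peak amplitude above a rolling-percentile baseline,
  depolarization duration/speed (onset→peak; amplitude/duration), calcium
  transient duration (CTD, 10 %-amplitude onset→end), and repolarization
  30/60/90 — the time from the peak until the signal has decayed by 30/60/90 %
  of the amplitude (APD30/60/90-style, linearly interpolated);
- QC filters: cells kept with 2000–7500 detected features (inclusive) and
  < 10 % mitochondrial reads; genes kept when expressed in ≥ 10 retained cells;
- cohort policy: two-tailed Mann–Whitney U when a group is small (n < 8),
  Welch's t otherwise; Student's t by explicit request.

## Worked example

```python
from ccopheno import OrganoidSimParams, make_organoid_video, segment_stack
from ccopheno.contraction import summarize_contraction

stack, truth = make_organoid_video(OrganoidSimParams(seed=7))
summary = summarize_contraction(segment_stack(stack))
print(summary.n_beats, truth.n_beats)
print(round(summary.contraction_frequency, 1))
print(round(summary.fs_mean, 2), round(truth.fractional_shortening, 2))
```

prints

```
30 30
61.3
7.34 7.5
```

— the detector recovers all 30 programmed beats of the 30 s recording, a
spontaneous rate of ~61 beats/min against the programmed 60, and a mean
fractional shortening of 7.34 % against a programmed 7.5 % (the wall thickens
7.5 % at peak systole). The scripts in `examples/` walk through contraction
kinetics, calcium kinetics, a treated-vs-control cohort and QC filtering,
each printing measured values next to programmed truth.

A thin CLI mirrors the library for shell use:

```bash
ccopheno simulate --seed 3 --outdir fixtures/
ccopheno contraction --input fixtures/organoid.tiff --outdir out/
ccopheno calcium --input fixtures/calcium.csv --outdir out/
ccopheno scqc --input fixtures/counts --outdir out/
```

All CSV outputs carry provenance headers (package version, seed, config
hash); identical config + seed reproduces byte-identical files.

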