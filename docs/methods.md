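# Methods notes

This note records the models, parameter choices, numerical conventions,
and known limitations behind `pupilstate`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Pupil preprocessing

Order of operations: blink interpolation → zero-phase 4th-order
Butterworth low-pass at 3.5 Hz → session z-score → cubic-spline upsample
10 → 100 Hz → zero-phase 4th-order Butterworth high-pass at 0.1 Hz.  The
low-pass precedes z-scoring so the session SD reflects the filtered
signal.  Blink gaps are filled linearly between the last pre-blink and
first post-blink samples (end gaps hold the nearest good value); cubic
alternatives were rejected because they can overshoot non-monotonically.
Traces shorter than 20 s, blink cover above 50%, and constant traces are
rejected (`DegenerateVarianceError` rather than silent NaN z-scores).

Two numerical conventions matter:

* **Upsampling grid.** The 100 Hz grid has exactly 10× the samples
  (6000 → 60 000) and is placed symmetrically about the span of the 10 Hz
  samples (it starts 0.045 s before the first sample).  An asymmetric grid
  anchored at the first sample would extend 0.09 s past the data on one
  side only and break the time-reversal contract below.
* **Zero-phase contract.** Preprocessing applied to a time-reversed trace
  equals the time-reversed preprocessed trace to 1e−8 away from the
  edges.  Achieving this takes two implementation choices: the low-pass
  runs with Gustafsson initial conditions (`filtfilt(method="gust")`),
  which are exactly reversal-equivariant — otherwise the session
  z-score statistics leak tiny edge asymmetries into the entire trace —
  and the 0.1 Hz high-pass runs as second-order sections, because in
  transfer-function form a 4th-order filter at a normalized cutoff of
  0.002 amplifies ~1e−12 input differences to ~1e−7.  "Away from the
  edges" means 100 s: the high-pass edge transient decays with a ~4 s
  time constant.

## Dilation detection

The detector is a literal sampled implementation of the three printed
criteria (10 s window sliding in 0.01 s steps; first 2 s continuously
below threshold; first supra-threshold local maximum is the peak; return
below threshold within 6 s after the peak; resume at the event offset).
Conventions:

* "Continuously below" is evaluated on samples (all 200 samples of the
  2 s span strictly below threshold); no sub-sample interpolation.
* A local maximum at sample *p* requires `v[p−1] < v[p]` and
  `v[p] ≥ v[p+1]`, which resolves plateaus to their first sample.
* The return check runs on the 6 s after the peak even beyond the
  detecting window; if the trace ends first, the event is rejected.
* Events whose ±6 s metric window leaves the trace are dropped but still
  consume their span of the search.
* Baseline/amplitude windows are half-open and left-inclusive:
  [−6, −4) and [−2.5, 2.5) s.

The implementation is vectorized with jump-ahead bookkeeping but is
provably step-equivalent to the naive scan; the test suite re-derives the
event set with an independent window-by-window oracle on 100 seeded
traces and requires exact agreement.

**Threshold nesting caveat.**  Event sets at thresholds 1.0 ⊂ 0.65 ⊂ 0.5
SD nest only when the trace returns below the *lowest* threshold between
events.  The baseline-stability criterion is stricter at lower
thresholds, so on traces whose baseline drifts within [0.5, 1.0) z an
event found at 1.0 SD can fail the 0.5 SD baseline check.  Nesting is
asserted under planted-event conditions (2.0 z events over 0.3 z drift),
where it holds.

**Evoked peaks** are trace maxima on `(onset, onset + 6 s]` (first index
on ties); overlapping search windows truncate at the next onset with a
warning.  The 6 s span is a package choice: evoked dilations resolve
within a few seconds of the 2 s stimulation train.  In mixed sessions the
spontaneous detector is blind to stimulation, so the pipeline reassigns
any spontaneous detection peaking inside a stimulation-response window to
the evoked detector.

## EEG spectra

* `window_psd` is a plain rectangular-window periodogram (density
  scaling) on exactly 1000 samples; `sum(psd)·Δf = mean(x²)` holds to
  float precision with DC/Nyquist bins not doubled.  A Hann taper is
  deliberately not the default: the band series is defined by the bare
  FFT periodogram.
* `sliding_band_power` steps 1 s windows by 10 samples; for N samples the
  series has (N − 1000)/10 + 1 points, timestamped at window centers
  (first timestamp 0.5 s), which aligns symmetrically with pupil peaks.
* Band areas use trapezoidal integration with endpoints included; the
  55–65 Hz notch gap belongs to no band, while total-power denominators
  integrate 1–100 Hz across the gap.
* The session-normalized spectrum averages periodograms of
  non-overlapping random 2 s segments (placed by the exact gap method,
  seeded) and divides by total 1–100 Hz power.  Normalization is isolated
  in one function because published "normalized PSD" conventions vary.

## Aperiodic parameterization

The knee model `log10 P(f) = b − log10(k + f^χ)` is fit on 2–55 Hz by
bounded nonlinear least squares with multi-start over χ₀ ∈ {0.5, 1, 2}
and k₀ ∈ {1e−3, 1, 10, 100}; a robust second pass drops the most
positive 2.5% of residuals (oscillatory peaks) and refits.  Gaussian
peaks are extracted iteratively from the flattened spectrum (tallest
first, up to 3), jointly refined, and the aperiodic component is refit on
the peak-removed spectrum.  Reported peak width is 2σ of the Gaussian,
bounded to [2, 10] Hz; minimum peak height is 0.1 log10-power.
Non-convergence returns a flagged fit with its achieved R².

Noiseless recovery over χ ∈ {0.5, 1, 1.5, 2} × k ∈ {0, 10} is exact to
machine precision (asserted at |error| ≤ 0.1).  When estimating from 1 s
windows, Fejér-kernel leakage smears steep spectra and biases the
*offset* upward by ~0.1; the exponent survives within 0.1.  Leakage-free
estimation (e.g., 4 s Welch segments) recovers both within 0.1.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes;
its defaults are the package's study conditions.

* **Dilation kernel**: difference of exponentials
  `exp(−t/τ_d) − exp(−t/τ_r)` normalized to unit peak, rise τ_r = 0.5 s,
  decay τ_d = 2.0 s — the slow-rise/slower-decay shape of phasic
  dilations.  Events are placed by their *peak* times.
* **Event amplitude** 2.0 z and **slow drift** SD 0.3 z.  The drift is
  Gaussian noise low-passed at 0.05 Hz — genuinely *sub-threshold* slow
  drift that the 0.1 Hz analysis high-pass removes.  A higher drift
  cutoff (e.g., 0.2 Hz) would leak through the high-pass: with these
  amplitudes the surviving ~0.3 z fluctuation would cross the 0.5 z
  threshold about every 25 s and no detector implementing the printed
  criteria could reach 95% precision.  The cutoff is configurable for
  stress-testing (the detector–oracle equivalence tests deliberately use
  0.25–0.45 Hz drift).
* **Spontaneous event times**: Poisson process with a hard refractory
  interval (default 12 s), mean interval equal to 1/rate.  A pure Poisson
  process puts ~11% of successive events within the 6 s return window,
  where the printed criteria cannot accept them; a refractory renewal
  process is also what the right-skewed interdilation histograms of real
  sessions (mean ≈ 30 s, median ≈ 22 s) look like.  Events are thinned
  within 10 s of a stimulation onset.
* **Stimulation**: onsets every 30 s starting at a random phase, 2 s
  trains; one evoked pupil peak 2.5 s after each onset (configurable
  latency).
* **EEG**: frequency-domain-shaped Gaussian noise whose expected
  periodogram is `10^b/(k + f^χ)` (defaults b = 2, k = 10, χ = 2, in
  µV²/Hz), plus per-band band-pass-filtered Gaussian noise scaled to the
  aperiodic band power and amplitude-modulated by
  `1 + gain_label · kernel(t − peak + lag)`, clipped at zero.  Default
  gains move power from low to high bands around dilations, more strongly
  for evoked events in the gamma bands.
* **Seeding**: one master seed; `SeedSequence` children per component.
  Identical configs reproduce sessions bit-for-bit.

**What the generator does not emulate**: eye blinks and video artifacts,
rapid-eye-movement periods, non-stationary arousal drifts, 1/f parameter
drift within a session, inter-animal variability, and volume-conducted
line-noise structure beyond a clean 60 Hz component.  Passing tests
therefore demonstrate algorithmic correctness and calibration on the
assumed signal structure, not robustness to every artifact of real
recordings.

**Timing-structure confound.**  With *equal nonzero* coupling gains for
both classes the two dilation types remain statistically separable:
spontaneous events cluster inside the 10 s gaps between
stimulation-exclusion zones, so a neighbor's envelope tail (kernel decay
2 s, still visible ~8 s out) enters the ±6 s aligned window more often
for spontaneous trials, and a linear classifier reaches ~0.6 accuracy.
The exchangeable null used for calibration checks therefore sets all
gains to zero (EEG independent of events).  Real datasets plausibly carry
the same confound — classifier accuracy partly reflects event-timing
statistics, not only oscillatory coupling.

## Statistics

* Pointwise comparisons are uncorrected two-sided unpaired t tests per
  time point, reported as counts and percentages; a Benjamini–Hochberg
  option exists but is off by default because the reporting convention is
  raw counts.  Zero-variance columns yield p = 1 with a warning.
* The statistical unit is the trial; session-level aggregation is a
  caller-side switch (pool per session before testing).
* Event-metric comparisons use Student's t tests with a Shapiro normality
  check falling back to the Mann–Whitney U test, as reported per metric.
* Pre/during/post windows are [−7.5, −2.5), [−2.5, 2.5), [2.5, 7.5) s;
  the pipeline extracts trials at a 7.5 s half-span and crops the central
  12 s for classification so both printed windows come from one
  extraction.

## Classification

* Stratified fivefold splits are a pure function of the labels and the
  seed, so fold memberships are identical across model kinds and bands.
* Per-feature standardization statistics come from the training folds
  only; the CNN's early-stopping validation slice (20%, stratified) is
  carved from the training folds.
* Accuracy thresholds probability outputs at 0.5 with ties to class 0.
* The CNN default is three conv blocks (16/32/64 filters, kernel 7,
  max-pool 3), global average pooling, a 64-unit dense ReLU layer, and a
  sigmoid output, trained with Adam (1e−3, minibatch 32, ≤100 epochs,
  patience 10).  This capacity suits cohorts of order 10² trials × 1200
  features on one CPU; wider stacks (e.g., 32/64/128) are a config away.
* The elastic-net baseline is penalized *logistic* regression (mixing
  0.5): the classification context calls for a classification loss; a
  squared-loss variant of the printed objective would not output class
  probabilities.
* The MLP baseline (scikit-learn) has 128/64 ReLU hidden layers with Adam
  and early stopping but no dropout or batch normalization.
* The random forest uses 500 trees, `min_samples_split=10`,
  `min_samples_leaf=5` (mid-range of the stated bounds), unbounded depth.
* SVM grid search: C ∈ {0.1, 1, 10, 100}, γ ∈ scale-heuristic ×
  {0.1, 1, 10}, inner 3-fold.

## Pipeline

Stages run in fixed order (ingest → pupil → detect → spectra → stats →
classify); each artifact is a CSV/JSON file registered in a manifest, and
a stage failure aborts with the stage name and the partial manifest.
Float formatting is fixed (`%.8g`) so identical config + seed reproduce
byte-identical artifacts; per-stage timings go to the log, never into the
manifest.  All child seeds derive from the master seed via
`SeedSequence`.

## Problem sizes

Defaults throughout the tests and the acceptance script are desk-scale
choices: 400–1800 s sessions, cohorts of ~150–200 trials from 4–5
sessions, 100 detector-equivalence traces of 600 s, and ~40 000–70 000
null column tests for calibration.  They are large enough to pin each
property at its stated tolerance while keeping a full run in minutes on
one CPU.

## Known limitations

* Rapid-eye-movement exclusion is not implemented (no operational
  criterion is available); REM-like pupil activity would be detected as
  ordinary dilations.
* The detection threshold is interpreted in *session* z units (the
  z-score computed before the 0.1 Hz high-pass), not re-normalized units
  of the high-passed trace.
* Normalized-spectrum comparisons are qualitative: the normalization
  convention (unit 1–100 Hz area) is one of several plausible readings.
* Single-channel contract: multi-channel montages are an outer loop, not
  handled internally.
* p-values from full-scale animal datasets are not reproducible from
  synthetic cohorts; the statistics modules are validated by calibration
  and directional contrasts instead.
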