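# Methods

## Problem and signal model

Chest compressions during CPR modulate the transthoracic impedance (TI)
measured through defibrillation pads: each compression produces a
fluctuation of roughly 0.5–2 ohms around the patient's baseline impedance,
synchronized with the compression itself.  AEDs store the TI after hardware
high-pass filtering that suppresses the (much larger) baseline, so the
working signal is a zero-centred trace in which compression activity appears
as a quasi-periodic oscillation at the compression rate (guideline target
100–120 cpm; field data span roughly 60–300 cpm), interrupted by pauses
(rhythm checks, ventilations, rescuer changes) and contaminated by slow
ventilation/motion residue and broadband noise.

The detector answers, every 2 s: *are compressions being delivered, and at
what rate?*  Aggregated over an episode this yields the chest compression
fraction (CCF — fraction of time with compressions) and the rate profile,
the core CPR-quality metrics.

## Detection pipeline

1. **Resampling.**  Input signals are polyphase-resampled to 250 Hz
   (anti-alias filtered when downsampling).
2. **Windowing.**  Consecutive, non-overlapping 2-s windows anchored at the
   episode start; a trailing partial window is discarded.  Two seconds
   guarantees ≥ 2 compressions per window at the slowest detectable rate
   (60 cpm), which an autocorrelation period estimate requires.
3. **Band limiting.**  One zero-phase 4th-order Butterworth low-pass at
   5 Hz over the whole episode (filtering once avoids per-window edge
   transients).  The cutoff keeps every detectable fundamental (250 cpm =
   4.17 Hz) while attenuating compression harmonics and noise.
4. **Per-window detrending.**  The least-squares line is subtracted from
   each window (`detrend="linear"`, default) rather than only the mean.
   Ventilation (~0.1–0.2 Hz) and baseline drift are nearly linear within
   2 s, so local detrending suppresses them without the multi-second edge
   transients that a sub-hertz zero-phase high-pass would inject into a 2-s
   window (measured: such a filter displaces the 60-cpm endpoint peak by a
   full lag sample).  `detrend="mean"` restores plain mean removal.
5. **Biased autocorrelation.**  `r[k] = (1/N) Σ x[n]x[n+k]` for lags
   0…1.0 s (+1 sample for boundary interpolation); dividing by the full
   window length N guarantees `|r[k]| ≤ r[0]`.  Windows whose total power is
   at the round-off floor relative to the raw window amplitude
   (`r[0] ≤ 1e-12·N·scale²`) are flagged null — this covers flat or
   disconnected-pad segments without dividing by ~0.
6. **Peak search (0.24–1.0 s).**  Candidates are strict local maxima of the
   overlap-normalized correlation
   `c[k] = Σ x[n]x[n+k] / √(E_left(k)·E_right(k))`, where `E_left`/`E_right`
   are the energies of the two segments the lag compares.  By Cauchy–Schwarz
   `|c[k]| ≤ 1`, with equality exactly when the window repeats itself at lag
   k; for any noiseless periodic fluctuation the score at the true period is
   ~1 at *every* lag.  This fixes the two systematic errors of thresholding
   `ρ[k] = r[k]/r[0]` directly: the triangular bias `(N−k)/N` both shrinks
   slow-rate peaks (a 60-cpm peak would score ~0.5) and drags their apparent
   position several lag samples early; the cruder compensation
   `ρ[k]·N/(N−k)` repairs stationary content but mislocates sparse
   pulse-train peaks, whose correlation envelope is not triangular.
   A range boundary qualifies as a peak only by exceeding its single
   interior neighbour; a plateau is represented by its first sample.  Among
   super-threshold candidates the **smallest lag** wins: the fundamental
   period is the shortest lag of self-similarity, and picking a multiple
   would halve the reported rate — the clinically dangerous error.
7. **Rate.**  `rate = 60 / lag` cpm.  With `refine_peak=True` (default) the
   integer-lag peak is refined by three-point parabolic interpolation
   (clamped to the lag range), shrinking the lag-grid quantization error —
   up to ~4 cpm at 250 cpm on the 250-Hz grid — to well under 1 cpm.  A
   window with no qualifying peak reports rate 0 ("no chest compressions"):
   during pauses the autocorrelation is disorganized and presents no
   prominent maximum.

Reported lags/scores are quantized to 1e-9 (rates to 1e-6 cpm) so results
are exactly reproducible under benign floating-point perturbations such as
rescaling the input; together with the normalized score this makes the
window decision exactly invariant to signal amplitude.

## Threshold calibration

The detection threshold applies to the overlap-normalized peak score.  It
was calibrated once on a dedicated synthetic corpus (30 episodes, master
seed 777 — disjoint from every seed used in the tests): windows fully inside
a compression series score ≥ ~0.82 (median 0.98), windows of pause content
(noise plus ventilation/drift residue) stay below 0.61 in 99% of cases, and
filtered pure-noise windows cross 0.70 in under ~1% of trials.  Sweeping the
threshold with the full evaluation protocol on that corpus, the worst of
Se/PPV/Sp/NPV is maximized near 0.70–0.75; the default is frozen at
**0.70**, keeping a margin below the weakest genuine compression window.
Windows that straddle a series boundary (partially filled with
compressions) populate the score band between the two classes and dominate
the residual errors on both sides.

## Synthetic episode generator

The generator emulates the statistical structure reported for AED corpora
of out-of-hospital cardiac arrest, so the pipeline is fully testable without
clinical recordings:

* **Session structure.**  Compression series of 15–60 s alternate with
  pauses of 3–20 s (drawn uniformly), rescaled so the continuous-time
  compression fraction equals the target CCF (default 0.68, the central
  value of such corpora).  Scenarios whose rescaled series cannot hold a
  compression raise a generation error naming the constraint.
* **Rates.**  Episode mean rates for benchmark corpora are drawn from a
  normal distribution centred at 173 cpm (sd 24.5, reproducing the reported
  157–190 IQR) truncated to the detectable 60–250 cpm span.  Within a
  series, inter-compression intervals carry Gaussian per-interval jitter
  (default sd 5 cpm) truncated at ±20% of the nominal period, keeping the
  instantaneous rate coherent inside any 2-s window, with a hard floor of
  0.2 s between compressions (~300 cpm).
* **Waveform.**  Each compression contributes an even, Hann-tapered pulse
  over one local period carrying the fundamental plus 2nd/3rd harmonics
  (default weights 0.25/0.1) — a quasi-sinusoidal trace that stresses the
  fundamental-vs-harmonic peak selection.  Annotated instants coincide with
  local extrema of the noiseless compression component.  Default amplitude
  1 ohm; the scale is arbitrary for the detector (scale-invariant) but sets
  the SNR against the 0.1-ohm Gaussian noise.  Ventilation (0.2 ohm at
  8/min) and drift (0.1 ohm at 0.05 Hz) model the slow artifacts that
  survive the device's baseline suppression.
* **Determinism.**  One `numpy` generator per scenario seed; benchmark
  episode seeds derive deterministically from a master seed.  Identical
  seeds give bit-identical signals and annotations.

What the generator does **not** model: real pad-contact noise signatures,
circulation (pulse) artifacts, shock transients, rescuer-specific waveform
asymmetries, and rate drift within a series.  Passing the synthetic
benchmark therefore demonstrates the algorithm's mechanics (periodicity
detection, rate accuracy, pause discrimination) under controlled SNR — it
does not certify clinical-grade performance, which in the field is
established on proprietary AED recordings.

## Evaluation protocol

* Windows are labeled `compressions` when ≥ 50% of the window overlaps
  annotated compression series (the labeling of straddling windows is a
  protocol choice; the fraction is configurable).
* TP = non-zero rate in a compression window, FP = non-zero rate in a
  no-compression window, FN/TN their zero-output counterparts.
  Se = 100·TP/(TP+FN), PPV = 100·TP/(TP+FP), Sp = 100·TN/(TN+FP),
  NPV = 100·TN/(TN+FN); a zero-denominator ratio is reported as undefined
  (never 0 or 100) and excluded from per-episode averaging.
* The per-window reference rate is `60·(n−1)/(t_last−t_first)` over the ≥ 2
  annotated instants inside the half-open window — the inverse of the mean
  time between compressions; TP windows with < 2 instants contribute to
  detection metrics but not to rate errors.  Signed error is reference
  minus estimate.  Windows whose reference rate exceeds the detector's
  250-cpm ceiling are scored by the plain TP/FN definitions and their count
  is flagged in the report.
* Per-episode CCF: reference = % of windows labeled compressions,
  estimate = % of windows with detections.
* Summaries: global metrics pool all windows; per-episode metrics carry
  normal-approximation 95% CIs (mean ± 1.96·sd/√n); rate and CCF errors are
  summarized as median (IQR) with numpy's linear quantile interpolation.
  Windows overlapping `excluded` annotation intervals (shocks, pad
  disconnections) are dropped before scoring.

## Numerical choices and edge cases

* Autocorrelation via `numpy.correlate` (exact direct form; verified
  against an explicit double-loop oracle to 1e-9 relative tolerance).
* Lag grid closed on both ends: k from ⌈0.24·fs⌉ to ⌊1.0·fs⌋ inclusive, so
  the printed 0.24 s and 1.0 s endpoints are themselves searchable.
* Signals shorter than one window produce an empty result list, not an
  error; an all-zero or constant episode produces all-zero outputs via the
  null-window floor.
* Parabolic refinement is skipped when the three-point curvature is
  non-negative or the implied shift exceeds half a sample.
* Benchmark problem sizes (50 episodes × 60 s for the noisy corpus; 60-s
  episodes per rate for the noiseless sweeps) were chosen to make every
  reported statistic stable at the percent level while keeping the
  whole suite fast.

## Known limitations

* At rates whose period approaches the window length (60 cpm = 2 periods
  per window), finite-window cross terms make the peak location sensitive
  to the waveform's phase: a pure sinusoid with a non-zero net linear
  component can land one lag sample off (±0.5 cpm).  Compression-like
  pulse trains do not show this sensitivity.
* Windows straddling a compression-series boundary are intrinsically
  ambiguous; the ≥ 50% labeling rule and the calibrated threshold resolve
  them consistently but they remain the dominant source of FP/FN.
* Rates above 250 cpm exist in field data but are outside the search range
  by design; such windows can only be detected as "compressions present"
  with a rate capped at 250 cpm (and are flagged in evaluation reports).
* The 2-s cadence bounds feedback latency; no streaming/real-time
  scheduling is implemented.
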