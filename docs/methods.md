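# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `retistim`, and the synthetic study conditions used by
the test suite and `scripts/acceptance.py`.

## Signal model and processing chain

### dF/F

The baseline frame is the per-pixel mean of *stimulus-free* frames — frames
outside every `[onset, onset + quiet_margin)` window (default margin 2 s,
matching the response window).  dF/F is `(F − F0)/F0` per pixel; baseline
pixels at or below a floor (default 1e−6) are masked to NaN and excluded
from ROI means and SDs rather than zero-filled, so dead camera pixels
cannot silently bias a trace.

### Photobleaching

Bleaching is modelled as a two-time-constant exponential.  The generator
uses the saturating form `B(t) = 1 − a1(1−e^(−t/τ1)) − a2(1−e^(−t/τ2))`
(so `B(0) = 1`); the analysis fits the equivalent offset+decay form
`c0 + a1·e^(−t/τ1) + a2·e^(−t/τ2)`, which avoids the scale/offset coupling
of fitting `B` directly.  The fit uses samples outside stimulus response
windows by default (whole-trace fitting is available via
`fit_segments_only=False`), is evaluated on all samples and subtracted.

Initialisation is deterministic: `c0` from the tail mean (last 10 % of
samples), `a1 = a2` at half the head-minus-tail excursion, `τ1`/`τ2` at
10 % and 60 % of the trace duration, `τ` bounded to [one frame period,
10 × duration], amplitudes bounded non-negative.  Time constants are
reported in canonical order `τ1 ≤ τ2`, resolving the exchange symmetry.
On non-convergence the model falls back to a single exponential, then a
straight line, recording which form was used.  The correction is idempotent
to well below 0.1 % of trace RMS.

### Response detection and thresholds

A pulse is scored on the ROI trace with the baseline window
`[onset − 2 s, onset)` (ending one frame before the pulse) and a response
window after the onset.  `response_amp` is the response-window *peak* minus
the baseline mean — a peak-excursion criterion, not an area — and a
response is detected when `response_amp > k·SD(baseline)` with k = 2.
The baseline SD is computed per trial (sample SD, n−1).

Repeats at one current are aggregated into a detection fraction; a current
qualifies at `min_fraction ≥ 0.5`.  The threshold is the lowest tested
current such that it *and every higher tested current* qualify (monotone
closure): an isolated low-current detection, typically a false positive,
cannot set the threshold.  If no current qualifies the estimate is flagged
"not reached" and excluded from group means (counted separately).

The default detection response window is 2 s (covers the GCaMP6f decay at
0.2 Hz pacing); the validation studies use 1 s, which still contains the
transient peak (rise τ ≈ 0.1 s) while halving the frames over which the
noise maximum is taken — relevant because a >2 SD *peak* criterion has a
substantial per-trial false-positive rate on white-noise traces (the
maximum of 10–20 Gaussian samples exceeds 2 SD in roughly 20–35 % of
trials).  The monotone closure plus repeat aggregation is what makes the
ladder estimate robust despite this.

### Activation maps and spread

The trial-level z map is
`z = (mean dF/F over response frames − mean over baseline frames) / SD over
baseline frames`, with the SD floored at 1e−4 dF/F units (floored pixels
counted and reported).  The response-window *mean* (not a per-frame max) is
used for the trial map because it stabilises the 2D fit at 10 fps; per-frame
maps appear only in the time-course analysis.

The spread fit is an axis-aligned 2D Gaussian with a free offset,
restricted to pixels with z above the threshold (default 2), initialised
from the moments of the suprathreshold mass, with positivity bounds on the
amplitude and sigmas.  Fewer than 10 suprathreshold pixels is a
"no activation" result, not an exception.  The activation *diameter* is the
arithmetic mean of the two axis FWHMs (`FWHM = 2√(2 ln 2)·σ`), in µm.
(The two natural readings of the FWHM statistic — radius or diameter — are
reconciled by always reporting the mean-FWHM value as a diameter and never
reporting a radius.)

Two practical regimes matter:

* **Truncation bias.**  When the peak z is within a few z-noise SDs of the
  threshold, the selection `observed z > 2` converts the Gaussian tail into
  a plateau near the cut; the free offset absorbs the plateau and the
  fitted σ shrinks (we observed ~25 % underestimation at peak z ≈ 4).  The
  estimator is reliable when peak z is ≳ 5–6× the threshold noise — i.e.
  for robust suprathreshold responses, which is how the validation studies
  are configured.
* **Brightness inhomogeneity.**  SD normalisation makes z scale with local
  brightness (brighter structures have smaller relative noise), so discrete
  bright somata spike the map and narrow the fit.  Spread is therefore best
  measured on the bulk fluorescence field; the spread scenarios use a
  uniform field with no discrete somata.

The diameter time course re-scores each response-window frame against the
same baseline statistics, records the per-frame diameter (0 for
"no activation"), and fits `A·exp(−(t−t0)²/2σ_t²)`; σ_t is the dynamics
statistic.  Fewer than 4 frames with a valid diameter, or σ_t pinned at its
bound (e.g. a time-constant spot), flags the fit invalid.  A Gaussian in
time (rather than an exponential) is used because the diameter series
rises and falls around the transient peak.

### Strength–duration fitting

The Lapicque model `I(d) = I_rh(1 + c/d)` is fitted by unweighted nonlinear
least squares in current space (the classical named form; points are
pooled across cells by default).  Start values are deterministic
(`I_rh` = minimum threshold, `c` = median duration) and both parameters are
bounded positive; a flat threshold-vs-duration curve drives `c` to a
negligible value on the tested duration scale and is flagged `at_bound`.
The Weiss charge alternative `Q(d) = I·d = I_rh(d + c)` is linear in `d`
and solved in closed form; standard errors come from the fit covariance
(delta method for the Weiss chronaxie ratio).  Group summaries use the
sample SD (n−1), reporting SD 0 for n = 1 groups.

### ERG

Epochs `[onset − 0.05 s, onset + 0.25 s)` are aligned by sample index and
averaged; partial epochs at the record edges are dropped and counted.  The
ERG amplitude is max − min of the averaged epoch (invariant to DC offset).
Oscillatory potentials are isolated with a 4th-order Butterworth 80–160 Hz
bandpass applied forward–backward (`sosfiltfilt`, odd-reflection padding):
the band is the defining choice; the order and zero-phase realisation are
implementation decisions recorded in code.  Zero-phase filtering squares
the magnitude response, giving ~1.0 gain at 120 Hz and < 1e−4 at 40 and
320 Hz.  The OP amplitude is max − min of the filtered epoch inside a
10–150 ms post-flash window, which avoids filter edge artefacts.  Averaging
precedes filtering (the amplitude is defined on the average signal); a
filter-then-average path exists but is off by default.

## Synthetic generator

The generator emulates: baseline fluorescence with additive Gaussian pixel
noise, double-exponential bleaching, stimulus-locked GCaMP6f-like
transients `(1 − e^(−t/τ_rise))·e^(−t/τ_decay)` (peak-normalised;
τ_rise = 0.1 s, τ_decay = 0.6 s by default), a Gaussian activation
footprint centred on a 30 µm electrode of a 200 µm-pitch MEA, sigmoidal
recruitment in current, and ERG epochs built from a negative a-lobe, a
positive b-lobe and a Gaussian-windowed 120 Hz wavelet with
`(I/I_max)^exponent` intensity scaling.  Identical spec + seed yields
bit-identical output; ground truth is returned alongside (and written as a
JSON sidecar next to TIFF/CSV outputs), so tests never re-derive truth from
the data.

Choices worth stating:

* **Gaussian, not Poisson, noise** — the detection criterion is SD-based,
  so Gaussian statistics match its assumptions and keep every recovery
  analysis tractable; `noise_sd` is expressed in the same camera units as
  `baseline_f0`.
* **All-or-none firing gate.**  Amplitude scales with the recruitment
  sigmoid `1/(1 + e^−(I−i50)/slope)`, but a cell produces *no* transient
  when the sigmoid is below `firing_gate` (default 0.05): spikes are
  all-or-none events and calcium amplitude grows with the number recruited.
  A pure sigmoid is positive at every current, which would make any
  noiseless detection criterion degenerate (every current "responds").
  The gate-crossing current `i50 + slope·logit(gate)` is the generated
  detection boundary recorded in the ground truth.
* **Default stimulus ladder** mirrors the experimental protocol: durations
  {0.1, 0.2, 0.5, 1} ms, currents 10–120 µA, 0.2 Hz repetition, ascending.
* **Cell placement** is uniform random with minimum-distance rejection so
  ROIs do not overlap.

What the generator does **not** emulate: biophysical network activation or
electric-field spread (recruitment is phenomenological), optics/PSF beyond
the Gaussian footprint, motion, correlated or signal-dependent noise, and
degeneration dynamics.  Passing recovery tests therefore demonstrate that
the estimators invert the stated forward model at realistic SNR — not that
they are robust to every artefact of real recordings.

## Validation study conditions

Problem sizes are chosen so the full battery runs in a few minutes on one
CPU.

* **Spread recovery** — 160×160 px at 1.6 µm/px, 10 fps, 10 s, uniform
  field, 5 % pixel noise, one 100 µA pulse at 6 s, peak dF/F 1.0 (a robust
  GCaMP6f burst; see the truncation-bias regime above), z-map response
  window 1 s, pre-onset baseline frames; footprints 105 µm and 60 µm,
  20 seeds each, acceptance band ±10 %.
* **Threshold recovery** — 32×32 px at 4 µm/px, one soma on the electrode,
  ladder {10, 15, 35, 50, 100} µA × 9 repeats at 0.2 Hz, recruitment
  midpoint 25 µA (slope 2 µA) so the generated boundary (19.1 µA) falls
  between the 15 and 35 µA rungs; 1 s response window.  The zero-noise arm
  is generated without bleaching and detected on raw dF/F — on a noiseless
  smooth trace any residual trend of the bleach fit trips the SD criterion
  (a pure linear trend scores ≈ 3.5 SD), so that arm isolates the
  detection/threshold logic; bleaching + correction are exercised in the
  noisy arm and in the dedicated bleach study.
* **Lapicque census** — 5 durations × 20 replicates, 5 % multiplicative
  lognormal noise, 200 seeded fits; both parameters within 10 % in ≥ 95 %.
* **Bleach fidelity** — 120 s traces at 10 fps; corrected RMS < 1 % of
  input on pure bleach; transient peak preserved within 5 % on
  bleach + transient.
* **Trend studies** — footprint FWHM {40, 70, 100} µm at currents
  {20, 50, 100} µA (diameter vs current non-decreasing); three cohorts with
  recruitment midpoints {18, 25, 40} µA, three cells each (group-mean
  thresholds preserve the order).
* **ERG contract** — non-overlapping 50 µV a-lobe and 120 µV b-lobe give a
  170 µV epoch amplitude within 1 %; zero-noise amplitudes strictly
  increase with intensity for a positive exponent.

## Known limitations

* The >2 SD peak criterion is a per-trial test with a high false-positive
  rate on uncorrelated noise; threshold estimates should always aggregate
  repeats.  Whether the original protocol computed the baseline SD per
  trial or per recording is not documented; per-trial is implemented.
* The suprathreshold-pixel Gaussian fit degrades gracefully but measurably
  near the detection limit (truncation bias above); diameters from maps
  whose peak z is < ~4 should be treated as lower bounds.
* No spike inference from calcium, no motion correction, no a/b-wave
  decomposition beyond the composite max − min amplitude, and no
  inferential statistics — tables report means, SDs and counts only.
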