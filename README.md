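# retistim

Analysis of electrically evoked retinal responses recorded optically
(GCaMP6f calcium imaging of retinal ganglion cells on a multi-electrode
array) and electrophysiologically (flash electroretinograms), together with
a ground-truth synthetic generator that makes every stage testable by
parameter recovery.

## Who this is for

Retinal-prosthesis and retinal-degeneration labs that stimulate ex-vivo
retina through an MEA (200 µm pitch, 30 µm electrodes; 0.1–1 ms cathodic
pulses, 10–120 µA, 0.2 Hz) while imaging RGC calcium signals at 10 frames/s,
and that track degeneration in vivo with flash ERGs (2 ms flashes at 2 Hz,
0.00978–640 cd·s/m²).

## What it computes

**dF/F pipeline** — the baseline frame is the per-pixel mean of
stimulus-free frames `F0(x,y)`; each frame becomes
`dF/F = (F − F0)/F0`; ROI traces are pixel averages, corrected for
photobleaching by fitting and subtracting a two-time-constant exponential
`c0 + a1·e^(−t/τ1) + a2·e^(−t/τ2)` on samples outside response windows.

**Response detection and thresholds** — a pulse responds when the
post-stimulus dF/F peak exceeds the pre-stimulus mean by more than
`k·SD` of the baseline (k = 2); the activation threshold is the lowest
tested current that responds consistently, with monotone closure over the
current ladder.

**Activation spread** — per-trial z-score maps
`z = (⟨dF/F⟩_response − ⟨dF/F⟩_baseline)/SD_baseline`; a 2D Gaussian
`A·exp(−(x−x0)²/2σx² − (y−y0)²/2σy²) + c` fitted to pixels with z > 2; the
activation diameter is the mean of the two axis FWHMs
(FWHM = 2√(2 ln 2)·σ).  Per-frame maps give the diameter time course and
its Gaussian-in-time width σ_t, the activation-dynamics statistic.

**Strength–duration curve** — the Lapicque hyperbola
`I(d) = I_rh·(1 + c/d)` fitted to (pulse duration, threshold) points yields
the rheobase `I_rh` and chronaxie `c` (Weiss charge form `Q = I_rh·(d + c)`
available as `model="weiss"`).

**ERG arm** — flash epochs averaged over ≥60 s records; ERG amplitude =
max − min of the averaged epoch; oscillatory potentials isolated with a
zero-phase 4th-order Butterworth 80–160 Hz bandpass; OP amplitude =
max − min of the filtered epoch in a 10–150 ms post-flash window;
amplitude–intensity tables per group.

**Synthetic generator** (`retistim.synth`) — movies with double-exponential
bleaching, shot-like Gaussian pixel noise, sigmoidally recruited
GCaMP6f-like transients and a Gaussian activation footprint centred on the
electrode; ERG records with a/b-wave lobes and a 120 Hz OP wavelet;
Lapicque-law strength–duration samples.  Every generator returns a
ground-truth sidecar.

## Worked example

```python
import numpy as np
from retistim import (
    CellSpec, MovieSpec, RoiSet, StimulusEvent, StimulusLog,
    make_stimulus_ladder, generate_movie,
    compute_baseline_frame, compute_dff_movie, extract_roi_traces,
    correct_photobleach, detect_response, estimate_threshold,
    compute_zscore_map, fit_gaussian2d, spread_diameter,
    generate_sd_points, fit_lapicque,
)

# --- activation threshold: one soma on a 30 um MEA electrode, 0.2 Hz ladder
stim = make_stimulus_ladder([10, 15, 35, 50, 100], n_reps=4, duration_us=100,
                            rate_hz=0.2, start_s=10.0)
spec = MovieSpec(height_px=64, width_px=64, um_per_px=2.0,
                 duration_s=stim.onsets_s[-1] + 5.0, noise_sd=50.0,
                 cells=[CellSpec((64.0, 64.0), 8.0)], spot_fwhm_um=60.0,
                 recruit_i50_uA=25.0, seed=0)
movie, truth = generate_movie(spec, stim)

baseline, base_idx = compute_baseline_frame(movie, stim, quiet_margin_s=2.0)
dff = compute_dff_movie(movie, baseline)
yy, xx = np.mgrid[0:64, 0:64]
soma = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 <= 4.0 ** 2
trace = extract_roi_traces(dff, RoiSet([("soma", soma)]), movie.frame_rate_hz)[0]
trace = correct_photobleach(trace, stim, response_window_s=2.0)

detections = [detect_response(trace, ev, baseline_window_s=2.0,
                              response_window_s=1.0, event_index=i)
              for i, ev in enumerate(stim)]
est = estimate_threshold(detections, min_fraction=0.5)
print(f"activation threshold: {est.threshold_uA:g} uA "
      f"(ground-truth boundary {truth.detection_boundary_uA:.1f} uA)")

# --- activation spread: z map of the bulk GCaMP field around the electrode
spot_spec = MovieSpec(height_px=96, width_px=96, um_per_px=2.0, duration_s=10.0,
                      noise_sd=50.0, background_level=1.0, cells=[],
                      spot_fwhm_um=60.0, resp_peak_dff=1.0, seed=0)
pulse = StimulusLog([StimulusEvent(6.0, 100.0, 100.0)])
spot_movie, spot_truth = generate_movie(spot_spec, pulse)
sbase, sidx = compute_baseline_frame(spot_movie, pulse, quiet_margin_s=2.0)
sdff = compute_dff_movie(spot_movie, sbase)
zmap = compute_zscore_map(sdff, sidx[sidx < 60], pulse.events[0],
                          spot_movie.frame_rate_hz, response_window_s=1.0)
fit = fit_gaussian2d(zmap, z_threshold=2.0)
diam = spread_diameter(fit, spot_movie.um_per_px)
print(f"activation diameter: {diam.diameter_um:.1f} um "
      f"(generated footprint {spot_truth.spot_fwhm_um:g} um)")

# --- strength-duration curve: rheobase and chronaxie
points = generate_sd_points(rheobase_uA=10.0, chronaxie_ms=0.2,
                            noise_cv=0.05, n_reps=20, seed=1)
print(fit_lapicque(points).summary())
```

prints

```
activation threshold: 35 uA (ground-truth boundary 19.1 uA)
activation diameter: 56.8 um (generated footprint 60 um)
Strength-duration fit (lapicque)
--------------------------------------------
rheobase (uA)             9.8812  +/- 0.1473
chronaxie (ms)            0.2040  +/- 0.0054
n points                      80
residual SS                51.07
```

The threshold lands on the 35 µA rung — the lowest tested current above the
generated 19.1 µA recruitment boundary on the {10, 15, 35, 50, 100} µA
ladder.  The fitted diameter recovers the 60 µm generated footprint within
the estimator's noise, and the Lapicque fit returns the generating
rheobase/chronaxie (10 µA, 0.2 ms) within their standard errors.

A command-line interface mirrors the library: `retistim simulate
movie|erg|sdpoints`, `retistim dff|threshold|spread|sdcurve|erg`, and
`retistim run` for the end-to-end pipeline (TIFF movie + stimulus CSV +
ROI masks in, trace/detection/threshold/spread tables and z maps out).

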