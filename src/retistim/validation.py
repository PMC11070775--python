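"""Synthetic validation studies: parameter-recovery scenarios with known truth.

Each function builds a ground-truth scenario with the generators in
:mod:`retistim.synth`, runs the corresponding analysis stage, and returns
the measured quantity next to the generating value.  They are used by the
test suite and by ``scripts/acceptance.py``; problem sizes are chosen so a
full battery runs in minutes on one CPU (see docs/methods.md).

Scenario conventions
--------------------
* Movies are imaged at 10 fps; stimulation is an ascending 0.2 Hz current
  ladder of 100 µs cathodic pulses.
* Spread scenarios view a uniform GCaMP field at 1.6 µm/px with a robust
  suprathreshold burst (peak dF/F 1.0) — the suprathreshold-pixel Gaussian
  fit needs peak z well above the z=2 cut to be well conditioned.
* Threshold scenarios use one soma on a 30 µm electrode, recruitment
  midpoint 25 µA (between the 15 and 35 µA rungs of the tested ladder) with
  2 µA slope, nine pulse repeats per current and a 1 s response window.
"""

from __future__ import annotations

import numpy as np

from .caimg import (
    StimulusEvent,
    StimulusLog,
    RoiSet,
    compute_baseline_frame,
    compute_dff_movie,
    correct_photobleach,
    detect_response,
    estimate_threshold,
    extract_roi_traces,
    DffTrace,
)
from .erg import (
    ErgTrace,
    analyze_erg_trace,
    amplitude_intensity_curve,
    design_op_filter,
    epoch_average,
    erg_amplitude,
)
from .sdcurve import fit_lapicque, group_thresholds
from .spatial import compute_zscore_map, diameter_vs_current, fit_gaussian2d, spread_diameter
from .synth import (
    CellSpec,
    ErgSpec,
    MovieSpec,
    bleach_curve,
    generate_erg,
    generate_movie,
    generate_sd_points,
    make_stimulus_ladder,
    transient_waveform,
)
from scipy import signal

__all__ = [
    "recover_spread_diameter",
    "recover_threshold",
    "lapicque_recovery_census",
    "bleach_correction_fidelity",
    "op_filter_gain",
    "diameter_current_monotonicity",
    "ordered_group_thresholds",
    "erg_amplitude_check",
]

LADDER_UA = (10.0, 15.0, 35.0, 50.0, 100.0)


# ---------------------------------------------------------------------------
# spread
# ---------------------------------------------------------------------------


def recover_spread_diameter(
    fwhm_um: float,
    seed: int,
    noise_frac: float = 0.05,
    um_per_px: float = 1.6,
) -> float:
    """Estimated activation diameter (µm) for a known Gaussian footprint."""
    spec = MovieSpec(
        height_px=160, width_px=160, um_per_px=um_per_px, duration_s=10.0,
        baseline_f0=1000.0, background_level=1.0, noise_sd=noise_frac * 1000.0,
        cells=[], spot_fwhm_um=fwhm_um, resp_peak_dff=1.0, seed=seed,
    )
    stim = StimulusLog([StimulusEvent(6.0, 100.0, 100.0)])
    movie, _ = generate_movie(spec, stim)
    baseline, base_idx = compute_baseline_frame(movie, stim, quiet_margin_s=2.0)
    pre_idx = base_idx[base_idx < 60]  # pre-onset frames only
    dff = compute_dff_movie(movie, baseline)
    zmap = compute_zscore_map(dff, pre_idx, stim.events[0], movie.frame_rate_hz,
                              response_window_s=1.0)
    fit = fit_gaussian2d(zmap, z_threshold=2.0)
    return spread_diameter(fit, um_per_px).diameter_um


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def _soma_roi(spec: MovieSpec) -> RoiSet:
    cell = spec.cells[0]
    H, W = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:H, 0:W]
    x_um = (xx + 0.5) * spec.um_per_px
    y_um = (yy + 0.5) * spec.um_per_px
    cx, cy = cell.center_xy_um
    mask = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= cell.radius_um**2
    return RoiSet([("soma", mask)])


def _threshold_movie_spec(noise_frac: float, seed: int,
                          i50_uA: float = 25.0, n_reps: int = 9) -> tuple[MovieSpec, StimulusLog]:
    fov_px = 32
    um_per_px = 4.0
    center = fov_px * um_per_px / 2.0
    stim = make_stimulus_ladder(LADDER_UA, n_reps=n_reps, duration_us=100.0,
                                rate_hz=0.2, start_s=10.0)
    duration = stim.onsets_s[-1] + 5.0
    bleach = dict() if noise_frac > 0 else dict(bleach_a1=0.0, bleach_a2=0.0)
    spec = MovieSpec(
        height_px=fov_px, width_px=fov_px, um_per_px=um_per_px,
        duration_s=duration, baseline_f0=1000.0, background_level=0.2,
        noise_sd=noise_frac * 1000.0,
        cells=[CellSpec((center, center), 8.0, 1.0)],
        spot_fwhm_um=60.0, recruit_i50_uA=i50_uA, recruit_slope_uA=2.0,
        resp_peak_dff=0.5, seed=seed, **bleach,
    )
    return spec, stim


def _threshold_estimate(noise_frac: float, seed: int,
                        i50_uA: float = 25.0, n_reps: int = 9):
    spec, stim = _threshold_movie_spec(noise_frac, seed, i50_uA, n_reps)
    movie, truth = generate_movie(spec, stim)
    baseline, _ = compute_baseline_frame(movie, stim, quiet_margin_s=2.0)
    dff = compute_dff_movie(movie, baseline)
    trace = extract_roi_traces(dff, _soma_roi(spec), movie.frame_rate_hz)[0]
    if noise_frac > 0:
        trace = correct_photobleach(trace, stim, response_window_s=2.0)
    dets = [
        detect_response(trace, ev, baseline_window_s=2.0, response_window_s=1.0,
                        event_index=i)
        for i, ev in enumerate(stim)
    ]
    est = estimate_threshold(dets, min_fraction=0.5)
    expected = truth.threshold_uA_by_duration["100.0"]
    return est, expected


def recover_threshold(noise_frac: float, seed: int,
                      i50_uA: float = 25.0, n_reps: int = 9) -> tuple[float | None, float]:
    """Estimated activation threshold (µA) and the generator's expected rung.

    Zero-noise movies are generated without bleaching and detected on raw
    dF/F; noisy movies keep the default bleaching and are corrected first.
    """
    est, expected = _threshold_estimate(noise_frac, seed, i50_uA, n_reps)
    return est.threshold_uA, expected


# ---------------------------------------------------------------------------
# strength-duration
# ---------------------------------------------------------------------------


def lapicque_recovery_census(
    n_runs: int = 200,
    rheobase_uA: float = 10.0,
    chronaxie_ms: float = 0.2,
    noise_cv: float = 0.05,
    n_reps: int = 20,
    seed: int = 0,
) -> float:
    """Fraction of seeded noisy fits with both parameters within 10 % of truth."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_runs):
        pts = generate_sd_points(rheobase_uA, chronaxie_ms,
                                 durations_ms=(0.1, 0.2, 0.3, 0.5, 1.0),
                                 noise_cv=noise_cv, n_reps=n_reps,
                                 seed=int(rng.integers(2**31)))
        res = fit_lapicque(pts)
        if (abs(res.rheobase_uA - rheobase_uA) <= 0.1 * rheobase_uA
                and abs(res.chronaxie_ms - chronaxie_ms) <= 0.1 * chronaxie_ms):
            ok += 1
    return ok / n_runs


# ---------------------------------------------------------------------------
# bleach correction
# ---------------------------------------------------------------------------


def bleach_correction_fidelity(seed: int = 0) -> tuple[float, float]:
    """(corrected/input RMS ratio on a pure bleach trace, transient-peak
    relative error on a bleach+transient trace)."""
    fs = 10.0
    t = np.arange(0, 120.0, 1.0 / fs)
    B = bleach_curve(t, 0.05, 5.0, 0.10, 60.0)
    pure = DffTrace("pure", t, B / B.mean() - 1.0)
    corr = correct_photobleach(pure, None)
    rms_ratio = float(np.sqrt(np.mean(corr.dff**2)) / np.sqrt(np.mean(pure.dff**2)))

    peak = 0.30
    onset = 60.0
    transient = peak * transient_waveform(t - onset, 0.1, 0.6)
    stim = StimulusLog([StimulusEvent(onset, 100.0, 100.0)])
    mixed = DffTrace("mixed", t, B / B.mean() - 1.0 + transient)
    corr2 = correct_photobleach(mixed, stim, response_window_s=3.0)
    win = (t >= onset) & (t < onset + 3.0)
    base = (t >= onset - 2.0) & (t < onset)
    measured = float(np.max(corr2.dff[win]) - np.mean(corr2.dff[base]))
    true_peak = float(np.max(transient))
    return rms_ratio, abs(measured - true_peak) / true_peak


# ---------------------------------------------------------------------------
# OP band filter
# ---------------------------------------------------------------------------


def op_filter_gain(freq_hz: float, fs: float = 2000.0, seed: int = 0,
                   band: tuple[float, float] = (80.0, 160.0)) -> float:
    """Measured amplitude gain of the zero-phase OP bandpass on a seeded sine."""
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(0, 4.0, 1.0 / fs)
    x = np.sin(2 * np.pi * freq_hz * t + phase)
    sos = design_op_filter(fs, band)
    y = signal.sosfiltfilt(sos, x)
    core = slice(x.size // 4, 3 * x.size // 4)  # avoid edge transients
    return float(np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2)))


# ---------------------------------------------------------------------------
# monotonic trends
# ---------------------------------------------------------------------------


def diameter_current_monotonicity(seed: int = 0) -> "pd.DataFrame":
    """Diameter-vs-current table for footprints widening with current.

    Emulates the observed growth of the activated area with stimulation
    current by generating one zero-noise movie per current whose footprint
    FWHM grows with the current.
    """
    currents = (20.0, 50.0, 100.0)
    fwhms = (40.0, 70.0, 100.0)
    pairs = []
    for cur, fwhm in zip(currents, fwhms):
        spec = MovieSpec(
            height_px=160, width_px=160, um_per_px=2.0, duration_s=10.0,
            baseline_f0=1000.0, background_level=1.0, noise_sd=0.0,
            bleach_a1=0.0, bleach_a2=0.0, cells=[], spot_fwhm_um=fwhm,
            resp_peak_dff=1.0, recruit_i50_uA=15.0, seed=seed,
        )
        stim = StimulusLog([StimulusEvent(6.0, cur, 100.0)])
        movie, _ = generate_movie(spec, stim)
        baseline, base_idx = compute_baseline_frame(movie, stim, 2.0)
        pre_idx = base_idx[base_idx < 60]
        dff = compute_dff_movie(movie, baseline)
        zmap = compute_zscore_map(dff, pre_idx, stim.events[0],
                                  movie.frame_rate_hz, response_window_s=1.0)
        fit = fit_gaussian2d(zmap, 2.0)
        pairs.append((cur, spread_diameter(fit, spec.um_per_px)))
    return diameter_vs_current(pairs)


def ordered_group_thresholds(seed: int = 0) -> "pd.DataFrame":
    """Group-mean thresholds for cohorts with ordered recruitment midpoints.

    Three synthetic cohorts (healthy-like through degenerated-like) with
    increasing recruitment midpoints, three cells each, zero noise; the
    group-mean activation thresholds must preserve the generating order.
    """
    group_i50 = {"A_low": 18.0, "B_mid": 25.0, "C_high": 40.0}
    estimates, groups = [], []
    for grp, i50 in group_i50.items():
        for k, jitter in enumerate((-1.0, 0.0, 1.0)):
            est, _ = _threshold_estimate(0.0, seed + k, i50_uA=i50 + jitter, n_reps=1)
            estimates.append(est)
            groups.append(grp)
    return group_thresholds(estimates, groups)


# ---------------------------------------------------------------------------
# ERG
# ---------------------------------------------------------------------------


def erg_amplitude_check(seed: int = 0) -> tuple[float, "pd.DataFrame"]:
    """(epoch amplitude for non-overlapping 50+120 µV lobes, zero-noise
    amplitude-intensity table for a positive intensity exponent)."""
    spec = ErgSpec(noise_sd_uv=0.0, op_amp_uv=0.0, intensities_cds_m2=[640.0],
                   a_amp_uv=50.0, b_amp_uv=120.0, seed=seed)
    traces, _ = generate_erg(spec)
    tr = ErgTrace(traces.time_s, traces.traces[640.0], traces.sampling_rate_hz,
                  traces.stim_onsets_s, 640.0)
    amp = erg_amplitude(epoch_average(tr))

    spec2 = ErgSpec(noise_sd_uv=0.0, op_amp_uv=10.0,
                    intensities_cds_m2=[0.00978, 1.0, 80.0, 640.0],
                    amp_vs_intensity_exponent=0.25, seed=seed)
    traces2, _ = generate_erg(spec2)
    metrics = [
        analyze_erg_trace(ErgTrace(traces2.time_s, v, traces2.sampling_rate_hz,
                                   traces2.stim_onsets_s, inten))
        for inten, v in traces2.traces.items()
    ]
    return amp, amplitude_intensity_curve(metrics)
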