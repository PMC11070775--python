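"""dF/F pipeline: baseline, dF/F, ROI traces, bleach correction, detection,
thresholds — trivial identities, generator-recovery checks and oracle
properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retistim import (
    DffTrace,
    FluorescenceMovie,
    RoiSet,
    StimulusEvent,
    StimulusLog,
    compute_baseline_frame,
    compute_dff_movie,
    correct_photobleach,
    detect_response,
    estimate_threshold,
    extract_roi_traces,
    generate_movie,
)
from retistim.synth import bleach_curve, transient_waveform


def _movie(frames, rate=10.0):
    return FluorescenceMovie(np.asarray(frames, float), rate, 1.0)


# --- baseline ---------------------------------------------------------------


def test_baseline_of_constant_movie_is_the_constant():
    movie = _movie(np.full((5, 4, 4), 7.0))
    base, idx = compute_baseline_frame(movie, StimulusLog([]), 2.0)
    assert np.array_equal(base, np.full((4, 4), 7.0))
    assert idx.tolist() == [0, 1, 2, 3, 4]


def test_baseline_excludes_response_window_frames():
    frames = np.stack([np.full((2, 2), v) for v in (10.0, 10.0, 30.0)])
    movie = _movie(frames, rate=1.0)  # frame 2 at t=2 s
    stim = StimulusLog([StimulusEvent(2.0, 50.0, 100.0)])
    base, idx = compute_baseline_frame(movie, stim, quiet_margin_s=1.0)
    assert np.array_equal(base, np.full((2, 2), 10.0))
    assert idx.tolist() == [0, 1]


def test_baseline_of_bleaching_movie_matches_time_mean(quiet_spec):
    spec = dataclasses.replace(quiet_spec, bleach_a1=0.05, bleach_a2=0.1, cells=[])
    movie, _ = generate_movie(spec, StimulusLog([]))
    base, _ = compute_baseline_frame(movie, StimulusLog([]), 2.0)
    t = movie.times_s
    expected = spec.baseline_f0 * spec.background_level * bleach_curve(
        t, 0.05, 5.0, 0.1, 60.0).mean()
    np.testing.assert_allclose(base, expected, rtol=1e-9)


def test_baseline_error_when_everything_stimulated():
    movie = _movie(np.ones((3, 2, 2)), rate=1.0)
    stim = StimulusLog([StimulusEvent(0.0, 50.0, 100.0)])
    with pytest.raises(ValueError, match="no baseline"):
        compute_baseline_frame(movie, stim, quiet_margin_s=10.0)


# --- dF/F -------------------------------------------------------------------


def test_dff_identity_and_scaling():
    base = np.full((3, 3), 50.0)
    frames = np.stack([base, 1.1 * base])
    dff = compute_dff_movie(frames, base)
    np.testing.assert_allclose(dff[0], 0.0, atol=1e-15)
    np.testing.assert_allclose(dff[1], 0.10, rtol=1e-12)


def test_dff_masks_zero_baseline_pixels():
    base = np.full((2, 2), 10.0)
    base[0, 0] = 0.0
    dff = compute_dff_movie(np.ones((2, 2, 2)), base)
    assert np.isnan(dff[:, 0, 0]).all()
    assert np.isfinite(dff[:, 1, 1]).all()
    with pytest.raises(ValueError, match="zero"):
        compute_dff_movie(np.ones((2, 2, 2)), np.zeros((2, 2)))


def test_dff_then_baseline_on_constant_movie_is_zero():
    movie = _movie(np.full((10, 4, 4), 123.0))
    base, _ = compute_baseline_frame(movie, StimulusLog([]), 2.0)
    dff = compute_dff_movie(movie, base)
    assert np.abs(dff).max() < 1e-14


# --- ROI traces -------------------------------------------------------------


def test_roi_trace_single_pixel_and_mean():
    dff = np.zeros((4, 2, 2))
    dff[:, 0, 0] = [0.0, 0.1, 0.2, 0.3]
    dff[:, 0, 1] = 0.2
    single = np.zeros((2, 2), bool)
    single[0, 0] = True
    pair = single.copy()
    pair[0, 1] = True
    traces = extract_roi_traces(dff, RoiSet([("a", single), ("b", pair)]), 10.0)
    np.testing.assert_allclose(traces[0].dff, [0.0, 0.1, 0.2, 0.3])
    np.testing.assert_allclose(traces[1].dff, [0.1, 0.15, 0.2, 0.25])


def test_roi_trace_all_masked_is_invalid():
    dff = np.full((3, 2, 2), np.nan)
    mask = np.ones((2, 2), bool)
    trace = extract_roi_traces(dff, RoiSet([("dead", mask)]), 10.0)[0]
    assert not trace.valid


def test_roi_peak_within_one_frame_of_generated_transient(quiet_spec, single_pulse):
    movie, _ = generate_movie(quiet_spec, single_pulse)
    base, _ = compute_baseline_frame(movie, single_pulse, 2.0)
    dff = compute_dff_movie(movie, base)
    mask = np.zeros((32, 32), bool)
    mask[14:18, 14:18] = True
    trace = extract_roi_traces(dff, RoiSet([("soma", mask)]), 10.0)[0]
    t_fine = np.linspace(0, 5, 5001)
    g = transient_waveform(t_fine, 0.1, 0.6)
    t_peak_true = 10.0 + t_fine[np.argmax(g)]
    t_peak = trace.time_s[np.argmax(trace.dff)]
    assert abs(t_peak - t_peak_true) <= 1.0 / movie.frame_rate_hz


# --- bleach correction ------------------------------------------------------


def test_bleach_fit_on_flat_trace_is_degenerate():
    t = np.arange(0, 30, 0.1)
    trace = DffTrace("flat", t, np.full(t.size, 0.05))
    out = correct_photobleach(trace, None)
    assert out.bleach_fit.c0 == pytest.approx(0.05, abs=1e-6)
    assert abs(out.bleach_fit.a1) < 1e-6 and abs(out.bleach_fit.a2) < 1e-6
    assert np.abs(out.dff).max() < 1e-6


def test_bleach_correction_removes_double_exponential():
    t = np.arange(0, 120, 0.1)
    B = bleach_curve(t, 0.05, 5.0, 0.10, 60.0)
    trace = DffTrace("bleach", t, B / B.mean() - 1.0)
    out = correct_photobleach(trace, None)
    assert np.sqrt(np.mean(out.dff**2)) < 0.01 * np.sqrt(np.mean(trace.dff**2))
    assert out.bleach_fit.model == "double_exp"
    assert out.bleach_fit.tau1_s <= out.bleach_fit.tau2_s


def test_bleach_correction_preserves_transient_peak():
    t = np.arange(0, 120, 0.1)
    B = bleach_curve(t, 0.05, 5.0, 0.10, 60.0)
    transient = 0.3 * transient_waveform(t - 60.0, 0.1, 0.6)
    stim = StimulusLog([StimulusEvent(60.0, 100.0, 100.0)])
    trace = DffTrace("mix", t, B / B.mean() - 1.0 + transient)
    out = correct_photobleach(trace, stim, response_window_s=3.0)
    win = (t >= 60.0) & (t < 63.0)
    base = (t >= 58.0) & (t < 60.0)
    peak = out.dff[win].max() - out.dff[base].mean()
    assert peak == pytest.approx(transient.max(), rel=0.05)


def test_bleach_correction_is_idempotent():
    t = np.arange(0, 60, 0.1)
    B = bleach_curve(t, 0.1, 3.0, 0.05, 30.0)
    trace = DffTrace("b", t, B / B.mean() - 1.0)
    once = correct_photobleach(trace, None)
    twice = correct_photobleach(once, None)
    rms_in = np.sqrt(np.mean(trace.dff**2))
    assert np.sqrt(np.mean((twice.dff - once.dff) ** 2)) < 1e-3 * rms_in


def test_bleach_correction_input_contracts():
    t = np.arange(0, 2.0, 0.5)
    trace = DffTrace("short", t, np.zeros(t.size))
    with pytest.raises(ValueError, match=">= 8 samples"):
        correct_photobleach(trace, None)
    t = np.arange(0, 10, 0.1)
    trace = DffTrace("covered", t, np.zeros(t.size))
    stim = StimulusLog([StimulusEvent(0.0, 50.0, 100.0)])
    with pytest.raises(ValueError, match="response windows"):
        correct_photobleach(trace, stim, response_window_s=20.0)


# --- detection --------------------------------------------------------------


def _trace_with(baseline_vals, response_vals, rate=10.0):
    y = np.concatenate([baseline_vals, response_vals])
    t = np.arange(y.size) / rate
    onset = len(baseline_vals) / rate
    return DffTrace("t", t, y), StimulusEvent(onset, 50.0, 100.0)


def test_detection_thresholding_against_baseline_sd():
    baseline = np.tile([0.0, 0.02], 10)  # mean 0.01, sd ~0.0103
    trace, ev = _trace_with(baseline, np.full(10, 0.06))
    det = detect_response(trace, ev, 2.0, 1.0)
    assert det.detected and det.response_amp == pytest.approx(0.05)
    trace2, ev2 = _trace_with(baseline, np.full(10, 0.025))
    det2 = detect_response(trace2, ev2, 2.0, 1.0)
    assert not det2.detected and det2.response_amp == pytest.approx(0.015)


def test_detection_window_contracts():
    trace, ev = _trace_with(np.zeros(2), np.zeros(5))
    with pytest.raises(ValueError, match=">= 3"):
        detect_response(trace, ev, 2.0, 1.0)


@settings(derandomize=True, max_examples=50)
@given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
def test_detection_is_scale_equivariant(scale, seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 0.01, 40)
    y[25] += rng.uniform(0, 0.05)
    t = np.arange(40) / 10.0
    ev = StimulusEvent(2.0, 50.0, 100.0)
    d1 = detect_response(DffTrace("a", t, y), ev, 2.0, 1.0)
    d2 = detect_response(DffTrace("a", t, scale * y), ev, 2.0, 1.0)
    assert d1.detected == d2.detected


# --- threshold estimation ---------------------------------------------------


def _dets(pattern, n_reps=1):
    """pattern: {current: detected_bool or fraction}."""
    out = []
    for cur, val in pattern.items():
        hits = round(val * n_reps) if not isinstance(val, bool) else (n_reps if val else 0)
        for i in range(n_reps):
            ev = StimulusEvent(len(out) * 5.0 + 1.0, float(cur), 100.0)
            from retistim.caimg import ResponseDetection

            out.append(ResponseDetection("c", len(out), ev, 0.1, 0.01, i < hits))
    return out


def test_threshold_matches_representative_ladder():
    est = estimate_threshold(_dets({10: False, 15: False, 35: True, 100: True}))
    assert est.threshold_uA == 35.0 and est.reached


def test_threshold_all_detected_gives_lowest_current():
    est = estimate_threshold(_dets({10: True, 15: True, 35: True}))
    assert est.threshold_uA == 10.0


def test_threshold_monotone_closure_discards_isolated_detection():
    est = estimate_threshold(_dets({10: True, 15: False, 35: True, 100: True}))
    assert est.threshold_uA == 35.0


def test_threshold_not_reached():
    est = estimate_threshold(_dets({10: False, 100: False}))
    assert not est.reached and est.threshold_uA is None


def test_threshold_rejects_mixed_durations_and_single_current():
    from retistim.caimg import ResponseDetection

    d1 = ResponseDetection("c", 0, StimulusEvent(1.0, 10.0, 100.0), 0.1, 0.01, True)
    d2 = ResponseDetection("c", 1, StimulusEvent(6.0, 20.0, 500.0), 0.1, 0.01, True)
    with pytest.raises(ValueError, match="mixed"):
        estimate_threshold([d1, d2])
    with pytest.raises(ValueError, match="2 distinct"):
        estimate_threshold([d1])


def _brute_force_threshold(currents, frac, min_fraction):
    for i, c in enumerate(currents):
        if all(f >= min_fraction for f in frac[i:]):
            return c
    return None


@settings(derandomize=True, max_examples=200)
@given(
    n_currents=st.integers(2, 6),
    pattern=st.integers(0, 2**18 - 1),
    n_reps=st.integers(1, 3),
)
def test_threshold_equals_brute_force_scan(n_currents, pattern, n_reps):
    currents = [10.0 * (i + 1) for i in range(n_currents)]
    dets = []
    from retistim.caimg import ResponseDetection

    k = 0
    for i, c in enumerate(currents):
        for r in range(n_reps):
            hit = bool((pattern >> (i * 3 + r)) & 1)
            dets.append(ResponseDetection(
                "c", k, StimulusEvent(k * 5.0 + 1.0, c, 100.0), 0.1, 0.01, hit))
            k += 1
    est = estimate_threshold(dets, min_fraction=0.5)
    frac = [np.mean([(d.detected) for d in dets if d.event.current_uA == c])
            for c in currents]
    assert est.threshold_uA == _brute_force_threshold(currents, frac, 0.5)


def test_end_to_end_zero_noise_threshold_recovery():
    from retistim.validation import recover_threshold

    thr, expected = recover_threshold(0.0, seed=0, n_reps=2)
    assert thr == expected == 35.0
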