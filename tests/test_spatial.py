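"""Activation maps and spread: z scoring, Gaussian fitting, FWHM diameters,
time course of the activated area."""

import dataclasses
import math

import numpy as np
import pytest

from retistim import (
    StimulusEvent,
    StimulusLog,
    compute_baseline_frame,
    compute_dff_movie,
    compute_zscore_map,
    diameter_vs_current,
    fit_gaussian2d,
    generate_movie,
    spread_diameter,
    spread_timecourse,
)
from retistim.spatial import FWHM_PER_SIGMA, Gaussian2DFit, closed_form_gaussian2d


def _gauss_map(shape, amp, x0, y0, sx, sy):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - x0) ** 2) / (2 * sx**2) - ((yy - y0) ** 2) / (2 * sy**2))


# --- z maps -----------------------------------------------------------------


def test_zscore_zero_when_response_equals_baseline():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 0.01, (20, 8, 8))
    stack = np.concatenate([base, base[:5]])
    ev = StimulusEvent(2.0, 50.0, 100.0)
    zm = compute_zscore_map(stack, np.arange(20), ev, 10.0, response_window_s=0.5)
    # response frames 20-24 repeat baseline frames 0-4: z is small, not extreme
    assert np.abs(np.nanmean(zm.z)) < 0.5


def test_zscore_value_matches_known_effect():
    rng = np.random.default_rng(1)
    base = rng.normal(0.0, 0.01, (200, 4, 4))
    resp = np.full((10, 4, 4), 0.03)
    stack = np.concatenate([base, resp])
    ev = StimulusEvent(20.0, 50.0, 100.0)
    zm = compute_zscore_map(stack, np.arange(200), ev, 10.0, response_window_s=1.0)
    assert np.all((zm.z > 2.6) & (zm.z < 3.4))


def test_zscore_peak_at_electrode_center(quiet_spec, single_pulse):
    spec = dataclasses.replace(quiet_spec, noise_sd=10.0, cells=[],
                               background_level=1.0, resp_peak_dff=1.0)
    movie, _ = generate_movie(spec, single_pulse)
    base, idx = compute_baseline_frame(movie, single_pulse, 2.0)
    dff = compute_dff_movie(movie, base)
    zm = compute_zscore_map(dff, idx[idx < 100], single_pulse.events[0], 10.0,
                            response_window_s=1.0)
    peak = np.unravel_index(np.nanargmax(zm.z), zm.z.shape)
    assert abs(peak[0] - 15.5) <= 1.5 and abs(peak[1] - 15.5) <= 1.5


def test_zscore_requires_variable_baseline():
    stack = np.zeros((30, 4, 4))
    ev = StimulusEvent(1.0, 50.0, 100.0)
    with pytest.raises(ValueError, match="zero everywhere"):
        compute_zscore_map(stack, np.arange(10), ev, 10.0)


def test_zscore_invariant_to_affine_intensity_rescaling(quiet_spec, single_pulse):
    """Gain and offset of the camera cancel in dF/F + z scoring."""
    spec = dataclasses.replace(quiet_spec, noise_sd=10.0, cells=[], background_level=1.0)
    movie, _ = generate_movie(spec, single_pulse)
    scaled = dataclasses.replace(movie, frames=movie.frames * 3.0)
    maps = []
    for m in (movie, scaled):
        base, idx = compute_baseline_frame(m, single_pulse, 2.0)
        dff = compute_dff_movie(m, base)
        maps.append(compute_zscore_map(dff, idx[idx < 100], single_pulse.events[0],
                                       10.0, response_window_s=1.0).z)
    np.testing.assert_allclose(maps[0], maps[1], rtol=1e-8)


# --- 2D Gaussian fit --------------------------------------------------------


def test_fit_recovers_noiseless_gaussian():
    z = _gauss_map((64, 64), 8.0, 30.0, 34.0, 4.0, 4.0)
    fit = fit_gaussian2d(z, 2.0)
    assert fit.sigma_x_px == pytest.approx(4.0, rel=1e-3)
    assert fit.sigma_y_px == pytest.approx(4.0, rel=1e-3)
    assert fit.x0_px == pytest.approx(30.0, abs=1e-3)


def test_fit_reports_no_activation_below_threshold():
    fit = fit_gaussian2d(np.full((32, 32), 1.0), 2.0)
    assert not fit.valid and "pixels above" in fit.reason


def test_fit_recovers_elongated_axis_ratio():
    z = _gauss_map((64, 64), 8.0, 32.0, 32.0, 8.0, 4.0)
    fit = fit_gaussian2d(z, 2.0)
    assert fit.sigma_x_px / fit.sigma_y_px == pytest.approx(2.0, rel=0.05)


def test_fit_matches_closed_form_oracle():
    z = _gauss_map((64, 64), 7.0, 31.0, 29.5, 5.0, 3.0)
    fit = fit_gaussian2d(z, 2.0)
    oracle = closed_form_gaussian2d(z, 2.0)
    for attr in ("amplitude", "x0_px", "y0_px", "sigma_x_px", "sigma_y_px"):
        assert getattr(fit, attr) == pytest.approx(getattr(oracle, attr), rel=1e-6, abs=1e-6)


# --- spread diameter --------------------------------------------------------


def test_fwhm_conversion():
    fit = Gaussian2DFit(5.0, 10.0, 10.0, 10.0, 10.0, 0.0, 0.0, 50)
    est = spread_diameter(fit, um_per_px=1.0)
    assert est.diameter_um == pytest.approx(23.548, abs=1e-3)


def test_diameter_is_mean_of_axis_fwhms():
    sx = 100.0 / FWHM_PER_SIGMA
    sy = 110.0 / FWHM_PER_SIGMA
    est = spread_diameter(Gaussian2DFit(5.0, 0, 0, sx, sy, 0, 0, 50), 1.0)
    assert est.diameter_um == pytest.approx(105.0)


def test_diameter_requires_calibration_and_valid_fit():
    fit = Gaussian2DFit(5.0, 0, 0, 2.0, 2.0, 0, 0, 50)
    with pytest.raises(ValueError, match="calibration"):
        spread_diameter(fit, 0.0)
    with pytest.raises(ValueError, match="invalid"):
        spread_diameter(Gaussian2DFit(valid=False), 1.0)


def test_isotropic_spot_rotation_invariance():
    z = _gauss_map((64, 64), 8.0, 25.0, 40.0, 5.0, 5.0)
    d1 = spread_diameter(fit_gaussian2d(z, 2.0), 1.0).diameter_um
    d2 = spread_diameter(fit_gaussian2d(np.rot90(z), 2.0), 1.0).diameter_um
    assert d1 == pytest.approx(d2, rel=1e-6)


def test_footprint_ordering_is_preserved(quiet_spec):
    from retistim.validation import recover_spread_diameter

    d_small = recover_spread_diameter(60.0, seed=0, noise_frac=0.0)
    d_large = recover_spread_diameter(105.0, seed=0, noise_frac=0.0)
    assert d_small < d_large
    assert d_small == pytest.approx(60.0, rel=0.02)
    assert d_large == pytest.approx(105.0, rel=0.02)


# --- time course ------------------------------------------------------------


def _timecourse(decay_tau, seed=0):
    from retistim import MovieSpec

    spec = MovieSpec(
        height_px=96, width_px=96, um_per_px=2.0, duration_s=10.0,
        baseline_f0=1000.0, background_level=1.0, noise_sd=10.0,
        bleach_a1=0.0, bleach_a2=0.0, cells=[], spot_fwhm_um=60.0,
        resp_peak_dff=1.0, resp_decay_tau_s=decay_tau, seed=seed,
    )
    stim = StimulusLog([StimulusEvent(6.0, 100.0, 100.0)])
    movie, _ = generate_movie(spec, stim)
    base, idx = compute_baseline_frame(movie, stim, 3.0)
    dff = compute_dff_movie(movie, base)
    return spread_timecourse(dff, idx[idx < 60], stim.events[0], 10.0, 2.0,
                             response_window_s=3.0)


def test_timecourse_faster_decay_gives_smaller_sigma_t():
    fast = _timecourse(0.3)
    slow = _timecourse(1.2)
    assert fast.n_valid_frames >= 4 and slow.n_valid_frames >= 4
    assert fast.sigma_t_s < slow.sigma_t_s


def test_timecourse_all_noise_movie_is_invalid():
    rng = np.random.default_rng(0)
    dff = rng.normal(0, 0.01, (80, 16, 16))
    ev = StimulusEvent(6.0, 50.0, 100.0)
    tc = spread_timecourse(dff, np.arange(50), ev, 10.0, 2.0)
    assert not tc.fit_valid and tc.n_valid_frames < 4


def test_timecourse_constant_spot_is_flagged():
    spot = _gauss_map((48, 48), 0.05, 24, 24, 6, 6)
    rng = np.random.default_rng(2)
    dff = rng.normal(0, 1e-3, (80, 48, 48)) + spot[None]
    dff[:40] -= spot[None]  # baseline frames without the spot
    ev = StimulusEvent(4.0, 50.0, 100.0)
    tc = spread_timecourse(dff, np.arange(40), ev, 10.0, 1.0, response_window_s=2.0)
    assert tc.n_valid_frames >= 4
    assert tc.at_bound and not tc.fit_valid


# --- diameter vs current ----------------------------------------------------


def test_diameter_vs_current_single_row_and_stats():
    f = Gaussian2DFit(5.0, 0, 0, 100.0 / FWHM_PER_SIGMA, 100.0 / FWHM_PER_SIGMA, 0, 0, 50)
    e100 = spread_diameter(f, 1.0)
    tab = diameter_vs_current([(20.0, e100)])
    assert len(tab) == 1 and tab.n[0] == 1 and tab.diameter_um_sd[0] == 0.0

    f2 = Gaussian2DFit(5.0, 0, 0, 110.0 / FWHM_PER_SIGMA, 110.0 / FWHM_PER_SIGMA, 0, 0, 50)
    tab2 = diameter_vs_current([(20.0, e100), (20.0, spread_diameter(f2, 1.0))])
    assert tab2.diameter_um_mean[0] == pytest.approx(105.0)
    assert tab2.diameter_um_sd[0] == pytest.approx(7.0711, abs=1e-3)


def test_diameter_vs_current_monotone_for_widening_footprints():
    from retistim.validation import diameter_current_monotonicity

    tab = diameter_current_monotonicity(seed=0)
    assert tab.current_uA.is_monotonic_increasing
    assert tab.diameter_um_mean.is_monotonic_increasing
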