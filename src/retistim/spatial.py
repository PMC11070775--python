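"""Z-score activation maps and spatial spread of evoked retinal activation.

A trial's activation map is the per-pixel z score of the response-window
dF/F against the stimulus-free baseline.  The activated area is summarised
by a 2D Gaussian fitted to pixels with z above a threshold (default 2); the
activation *diameter* is the mean of the two axis FWHMs (2·sqrt(2 ln 2)·σ).
Per-frame maps give the diameter time course, whose Gaussian-in-time width
σ_t is the activation-dynamics statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .caimg import FluorescenceMovie, StimulusEvent

__all__ = [
    "ZScoreMap",
    "Gaussian2D",
    "Gaussian2DFit",
    "SpreadEstimate",
    "SpreadTimeCourse",
    "compute_zscore_map",
    "fit_gaussian2d",
    "closed_form_gaussian2d",
    "spread_diameter",
    "spread_timecourse",
    "diameter_vs_current",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class ZScoreMap:
    """Per-trial activation map: (response mean − baseline mean) / baseline SD."""

    z: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    n_floored: int
    sd_floor: float
    event: StimulusEvent | None = None


@dataclass
class Gaussian2DFit:
    """Result of fitting ``A·exp(−(x−x0)²/2σx² − (y−y0)²/2σy²) + offset``.

    Coordinates and sigmas are in pixels; :func:`spread_diameter` converts
    to micrometres.  ``valid`` is False for a "no activation" outcome (too
    few suprathreshold pixels); ``converged`` is False for a failed fit.
    """

    amplitude: float = np.nan
    x0_px: float = np.nan
    y0_px: float = np.nan
    sigma_x_px: float = np.nan
    sigma_y_px: float = np.nan
    offset: float = np.nan
    rss: float = np.nan
    n_pixels_fit: int = 0
    valid: bool = True
    converged: bool = True
    reason: str = ""

    def predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _gauss2d((np.asarray(x, float), np.asarray(y, float)),
                        self.amplitude, self.x0_px, self.y0_px,
                        self.sigma_x_px, self.sigma_y_px, self.offset)

    def summary(self) -> str:
        if not self.valid:
            return f"Gaussian2DFit: no activation ({self.reason})"
        lines = [
            "2D Gaussian activation fit",
            "-" * 40,
            f"{'amplitude (z)':<22}{self.amplitude:12.4f}",
            f"{'center x (px)':<22}{self.x0_px:12.4f}",
            f"{'center y (px)':<22}{self.y0_px:12.4f}",
            f"{'sigma x (px)':<22}{self.sigma_x_px:12.4f}",
            f"{'sigma y (px)':<22}{self.sigma_y_px:12.4f}",
            f"{'offset (z)':<22}{self.offset:12.4f}",
            f"{'pixels fitted':<22}{self.n_pixels_fit:12d}",
            f"{'residual SS':<22}{self.rss:12.4g}",
        ]
        return "\n".join(lines)


@dataclass
class SpreadEstimate:
    """Activation diameter: arithmetic mean of the two axis FWHMs, in µm."""

    diameter_um: float
    fwhm_x_um: float
    fwhm_y_um: float
    fit: Gaussian2DFit


@dataclass
class SpreadTimeCourse:
    """Per-frame activation diameters and their Gaussian-in-time fit."""

    time_s: np.ndarray
    diameter_um: np.ndarray
    amplitude_um: float = np.nan
    peak_time_s: float = np.nan
    sigma_t_s: float = np.nan
    fit_valid: bool = False
    at_bound: bool = False
    n_valid_frames: int = 0


# ---------------------------------------------------------------------------
# z maps
# ---------------------------------------------------------------------------


def compute_zscore_map(
    dff: np.ndarray,
    baseline_idx: np.ndarray,
    event: StimulusEvent,
    frame_rate_hz: float,
    response_window_s: float = 2.0,
    sd_floor: float = 1e-4,
    t0_s: float = 0.0,
) -> ZScoreMap:
    """Trial-level z map from a dF/F stack.

    ``z = (mean dF/F over response frames − mean over baseline frames) /
    SD over baseline frames``, with the SD floored at ``sd_floor`` (floored
    pixel count recorded).  Needs >= 3 baseline frames.
    """
    baseline_idx = np.asarray(baseline_idx)
    if baseline_idx.size < 3:
        raise ValueError("need >= 3 baseline frames for a z map")
    t = t0_s + np.arange(dff.shape[0]) / frame_rate_hz
    resp = (t >= event.onset_s) & (t < event.onset_s + response_window_s)
    if not resp.any():
        raise ValueError("response window contains no frames")
    base_stack = dff[baseline_idx]
    base_mean = np.nanmean(base_stack, axis=0)
    base_sd = np.nanstd(base_stack, axis=0, ddof=1)
    finite = np.isfinite(base_sd)
    if not (base_sd[finite] > 0).any():
        raise ValueError("baseline SD is zero everywhere; cannot normalise")
    n_floored = int(np.sum(finite & (base_sd < sd_floor)))
    sd = np.where(base_sd < sd_floor, sd_floor, base_sd)
    resp_mean = np.nanmean(dff[resp], axis=0)
    z = (resp_mean - base_mean) / sd
    return ZScoreMap(z, base_mean, base_sd, n_floored, sd_floor, event)


# ---------------------------------------------------------------------------
# 2D Gaussian model
# ---------------------------------------------------------------------------


def _gauss2d(xy, amp, x0, y0, sx, sy, off):
    x, y = xy
    return amp * np.exp(-((x - x0) ** 2) / (2 * sx**2)
                        - ((y - y0) ** 2) / (2 * sy**2)) + off


class Gaussian2D:
    """Axis-aligned 2D Gaussian model of an activation map.

    Follows the Model/Results idiom: construct from a z map (or bare 2D
    array), then :meth:`fit` returns a :class:`Gaussian2DFit`.  The fit is
    restricted to pixels with z above ``z_threshold`` and keeps an offset
    term; initialisation is from the moments of the suprathreshold mass, so
    the fit is deterministic.
    """

    def __init__(self, zmap: ZScoreMap | np.ndarray, z_threshold: float = 2.0,
                 min_pixels: int = 10):
        self.z = zmap.z if isinstance(zmap, ZScoreMap) else np.asarray(zmap, float)
        if self.z.ndim != 2:
            raise ValueError("z map must be 2D")
        self.z_threshold = z_threshold
        self.min_pixels = min_pixels

    def fit(self) -> Gaussian2DFit:
        z = self.z
        H, W = z.shape
        sel = np.isfinite(z) & (z > self.z_threshold)
        n = int(sel.sum())
        if n < self.min_pixels:
            return Gaussian2DFit(valid=False, n_pixels_fit=n,
                                 reason=f"{n} pixels above z={self.z_threshold}")
        yy, xx = np.nonzero(sel)
        vals = z[sel]
        w = vals - vals.min() + 1e-12
        x0 = float(np.sum(w * xx) / w.sum())
        y0 = float(np.sum(w * yy) / w.sum())
        sx = math.sqrt(max(float(np.sum(w * (xx - x0) ** 2) / w.sum()), 0.25))
        sy = math.sqrt(max(float(np.sum(w * (yy - y0) ** 2) / w.sum()), 0.25))
        p0 = [float(vals.max()), x0, y0, sx, sy, 0.0]
        big = 4.0 * max(H, W)
        lb = [0.0, -W, -H, 0.3, 0.3, -np.inf]
        ub = [np.inf, 2 * W, 2 * H, big, big, np.inf]
        try:
            popt, _ = curve_fit(
                _gauss2d, (xx.astype(float), yy.astype(float)), vals,
                p0=p0, bounds=(lb, ub), maxfev=20000,
            )
        except RuntimeError:
            return Gaussian2DFit(valid=True, converged=False, n_pixels_fit=n,
                                 reason="fit did not converge")
        resid = vals - _gauss2d((xx, yy), *popt)
        return Gaussian2DFit(
            amplitude=float(popt[0]), x0_px=float(popt[1]), y0_px=float(popt[2]),
            sigma_x_px=float(popt[3]), sigma_y_px=float(popt[4]),
            offset=float(popt[5]), rss=float(resid @ resid), n_pixels_fit=n,
        )


def fit_gaussian2d(zmap: ZScoreMap | np.ndarray, z_threshold: float = 2.0,
                   min_pixels: int = 10) -> Gaussian2DFit:
    """Fit a 2D Gaussian to suprathreshold pixels of a z map."""
    return Gaussian2D(zmap, z_threshold=z_threshold, min_pixels=min_pixels).fit()


def closed_form_gaussian2d(
    zmap: ZScoreMap | np.ndarray, z_threshold: float = 2.0
) -> Gaussian2DFit:
    """Exact log-quadratic solution for a noiseless zero-offset Gaussian map.

    ``ln z`` is a quadratic in (x, y); linear least squares on the
    suprathreshold pixels recovers amplitude, centre and sigmas exactly when
    the map is a pure sampled Gaussian.  Serves as the independent
    closed-form oracle for the nonlinear fit.
    """
    z = zmap.z if isinstance(zmap, ZScoreMap) else np.asarray(zmap, float)
    sel = np.isfinite(z) & (z > max(z_threshold, 1e-300))
    if sel.sum() < 6:
        return Gaussian2DFit(valid=False, n_pixels_fit=int(sel.sum()),
                             reason="too few pixels for closed form")
    yy, xx = np.nonzero(sel)
    x = xx.astype(float)
    y = yy.astype(float)
    L = np.log(z[sel])
    A = np.column_stack([np.ones_like(x), x, y, x**2, y**2])
    coef, *_ = np.linalg.lstsq(A, L, rcond=None)
    c, bx, by, ax, ay = coef
    if ax >= 0 or ay >= 0:
        return Gaussian2DFit(valid=True, converged=False, n_pixels_fit=int(sel.sum()),
                             reason="non-concave log surface")
    sx = math.sqrt(-1.0 / (2.0 * ax))
    sy = math.sqrt(-1.0 / (2.0 * ay))
    x0 = -bx / (2.0 * ax)
    y0 = -by / (2.0 * ay)
    amp = math.exp(c + x0**2 / (2 * sx**2) + y0**2 / (2 * sy**2))
    resid = z[sel] - _gauss2d((x, y), amp, x0, y0, sx, sy, 0.0)
    return Gaussian2DFit(amp, x0, y0, sx, sy, 0.0, float(resid @ resid),
                         int(sel.sum()))


# ---------------------------------------------------------------------------
# spread measures
# ---------------------------------------------------------------------------


def spread_diameter(fit: Gaussian2DFit, um_per_px: float) -> SpreadEstimate:
    """Activation diameter: mean of the two axis FWHMs, in micrometres."""
    if um_per_px is None or um_per_px <= 0:
        raise ValueError("spatial calibration (um_per_px) required")
    if not fit.valid or not fit.converged:
        raise ValueError("cannot derive a diameter from an invalid fit")
    fx = FWHM_PER_SIGMA * fit.sigma_x_px * um_per_px
    fy = FWHM_PER_SIGMA * fit.sigma_y_px * um_per_px
    return SpreadEstimate((fx + fy) / 2.0, fx, fy, fit)


def _time_gauss(t, A, t0, sigma):
    return A * np.exp(-((t - t0) ** 2) / (2 * sigma**2))


def spread_timecourse(
    dff: np.ndarray,
    baseline_idx: np.ndarray,
    event: StimulusEvent,
    frame_rate_hz: float,
    um_per_px: float,
    response_window_s: float = 2.0,
    z_threshold: float = 2.0,
    sd_floor: float = 1e-4,
    min_pixels: int = 10,
    t0_s: float = 0.0,
) -> SpreadTimeCourse:
    """Per-frame activation diameter and its Gaussian-in-time width σ_t.

    Each response-window frame is z scored against the same baseline stats
    and fitted as a 2D Gaussian; frames with "no activation" contribute
    diameter 0.  The diameter-vs-time series is then fitted to
    ``A·exp(−(t−t0)²/2σt²)``; fewer than 4 frames with a valid diameter, or a
    σ_t pinned at its bound (e.g. a time-constant spot), flags the fit.
    """
    baseline_idx = np.asarray(baseline_idx)
    if baseline_idx.size < 3:
        raise ValueError("need >= 3 baseline frames")
    t = t0_s + np.arange(dff.shape[0]) / frame_rate_hz
    resp_idx = np.nonzero((t >= event.onset_s) & (t < event.onset_s + response_window_s))[0]
    if resp_idx.size == 0:
        raise ValueError("response window contains no frames")
    base_stack = dff[baseline_idx]
    base_mean = np.nanmean(base_stack, axis=0)
    base_sd = np.nanstd(base_stack, axis=0, ddof=1)
    sd = np.where(base_sd < sd_floor, sd_floor, base_sd)

    times = t[resp_idx] - event.onset_s
    diam = np.zeros(resp_idx.size)
    n_valid = 0
    for j, fi in enumerate(resp_idx):
        zf = (dff[fi] - base_mean) / sd
        fit = fit_gaussian2d(zf, z_threshold=z_threshold, min_pixels=min_pixels)
        if fit.valid and fit.converged:
            diam[j] = spread_diameter(fit, um_per_px).diameter_um
            n_valid += 1

    tc = SpreadTimeCourse(times, diam, n_valid_frames=n_valid)
    if n_valid < 4:
        return tc
    span = times[-1] - times[0] if times.size > 1 else 1.0
    sig_lo = 0.25 / frame_rate_hz
    sig_hi = 10.0 * max(span, 1.0 / frame_rate_hz)
    p0 = [float(diam.max()), float(times[np.argmax(diam)]), max(span / 4.0, sig_lo * 2)]
    try:
        popt, _ = curve_fit(
            _time_gauss, times, diam, p0=p0,
            bounds=([0.0, times[0] - span, sig_lo], [np.inf, times[-1] + span, sig_hi]),
            maxfev=20000,
        )
    except RuntimeError:
        return tc
    A, t0f, sigma = (float(v) for v in popt)
    at_bound = sigma >= 0.99 * sig_hi or sigma <= 1.01 * sig_lo
    tc.amplitude_um, tc.peak_time_s, tc.sigma_t_s = A, t0f, sigma
    tc.at_bound = at_bound
    tc.fit_valid = not at_bound
    return tc


def diameter_vs_current(
    estimates: dict[float, list[SpreadEstimate]] | list[tuple[float, SpreadEstimate]],
) -> pd.DataFrame:
    """Table of mean activation diameter per stimulation current.

    Accepts either ``{current: [SpreadEstimate, ...]}`` or a flat list of
    ``(current, SpreadEstimate)`` pairs.  Columns: current_uA,
    diameter_um_mean, diameter_um_sd (sample SD, 0 for n=1), n.  Sorted by
    current; empty groups skipped.
    """
    if isinstance(estimates, dict):
        groups = estimates
    else:
        groups = {}
        for cur, est in estimates:
            groups.setdefault(float(cur), []).append(est)
    rows = []
    for cur in sorted(groups):
        vals = np.array([e.diameter_um for e in groups[cur]])
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(dict(current_uA=cur, diameter_um_mean=float(vals.mean()),
                         diameter_um_sd=sd, n=int(vals.size)))
    return pd.DataFrame(rows, columns=["current_uA", "diameter_um_mean",
                                       "diameter_um_sd", "n"])
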