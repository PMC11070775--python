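"""Core dF/F pipeline for optically recorded, electrically evoked retinal responses.

The processing chain mirrors standard GCaMP calcium-imaging practice for
ex-vivo retina on a multi-electrode array:

1. a baseline frame is computed as the per-pixel mean of stimulus-free frames;
2. every frame is converted to a fractional change dF/F against that baseline;
3. regions of interest (RGC somata) are averaged into traces;
4. traces are corrected for photobleaching by fitting and subtracting a
   two-time-constant exponential;
5. a pulse is scored as a response when the post-stimulus peak exceeds
   ``criterion_k`` (default 2) baseline standard deviations;
6. the activation threshold is the lowest tested current that responds
   consistently, with monotone closure over the current ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceMovie",
    "StimulusEvent",
    "StimulusLog",
    "RoiSet",
    "DffTrace",
    "BleachFit",
    "ResponseDetection",
    "ThresholdEstimate",
    "compute_baseline_frame",
    "compute_dff_movie",
    "extract_roi_traces",
    "correct_photobleach",
    "detect_response",
    "estimate_threshold",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FluorescenceMovie:
    """Single-channel fluorescence stack.

    Parameters
    ----------
    frames : (T, H, W) ndarray
        Intensity stack, arbitrary camera units, all values >= 0.
    frame_rate_hz : float
        Acquisition rate (10 fps for the recordings this package targets).
    um_per_px : float
        Spatial calibration, micrometres per pixel.
    t0_s : float
        Acquisition start time; stimulus-log times share this clock.
    """

    frames: np.ndarray
    frame_rate_hz: float
    um_per_px: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a (T>=2, H, W) stack")
        if np.nanmin(self.frames) < 0:
            raise ValueError("fluorescence intensities must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds from acquisition start."""
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class StimulusEvent:
    """One electrical pulse: onset (s), amplitude (µA), width (µs)."""

    onset_s: float
    current_uA: float
    duration_us: float
    polarity: str = "cathodic"
    electrode_id: int = 0

    def __post_init__(self) -> None:
        if self.current_uA <= 0:
            raise ValueError("current_uA must be > 0")
        if self.duration_us <= 0:
            raise ValueError("duration_us must be > 0")


@dataclass
class StimulusLog:
    """Ordered electrical pulse events anchoring epoch windows."""

    events: list[StimulusEvent]

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)


@dataclass
class RoiSet:
    """Labelled pixel masks, each a boolean (H, W) array."""

    rois: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        for label, mask in self.rois:
            if mask.dtype != bool:
                raise ValueError(f"ROI {label!r}: mask must be boolean")
            if not mask.any():
                raise ValueError(f"ROI {label!r}: mask is empty")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


@dataclass
class BleachFit:
    """Two-time-constant photobleaching fit ``c0 + a1 e^(-t/tau1) + a2 e^(-t/tau2)``.

    ``tau1_s <= tau2_s`` canonically. ``model`` records which form was
    actually used ("double_exp", or the "single_exp"/"linear" fallbacks).
    """

    c0: float
    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    rss: float
    model: str = "double_exp"

    def __post_init__(self) -> None:
        if self.model in ("double_exp", "single_exp") and (
            self.tau1_s <= 0 or self.tau2_s <= 0
        ):
            raise ValueError("time constants must be > 0")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            # (c0, a1) reused as (intercept, slope)
            return self.c0 + self.a1 * t
        return (
            self.c0
            + self.a1 * np.exp(-t / self.tau1_s)
            + self.a2 * np.exp(-t / self.tau2_s)
        )


@dataclass
class DffTrace:
    """Per-ROI fractional fluorescence change (0.01 == 1 %)."""

    label: str
    time_s: np.ndarray
    dff: np.ndarray
    bleach_corrected: bool = False
    bleach_fit: BleachFit | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.time_s.shape != self.dff.shape:
            raise ValueError("time_s and dff must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")


@dataclass
class ResponseDetection:
    """Outcome of the >k·SD response criterion for one pulse."""

    label: str
    event_index: int
    event: StimulusEvent
    response_amp: float
    baseline_sd: float
    detected: bool
    criterion_k: float = 2.0


@dataclass
class ThresholdEstimate:
    """Activation threshold for one ROI at one pulse duration.

    ``threshold_uA`` is one of the tested currents, or None when not reached.
    """

    label: str
    duration_us: float
    threshold_uA: float | None
    tested_currents_uA: np.ndarray
    detection_fraction: np.ndarray
    reached: bool
    min_fraction: float = 0.5


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def stimulus_free_frames(
    movie: FluorescenceMovie, stim: StimulusLog, quiet_margin_s: float
) -> np.ndarray:
    """Indices of frames outside every [onset, onset + quiet_margin_s) window."""
    t = movie.times_s
    free = np.ones(movie.n_frames, dtype=bool)
    for ev in stim:
        free &= ~((t >= ev.onset_s) & (t < ev.onset_s + quiet_margin_s))
    return np.nonzero(free)[0]


def compute_baseline_frame(
    movie: FluorescenceMovie,
    stim: StimulusLog,
    quiet_margin_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean of the stimulus-free frames.

    Returns the baseline image and the index set of frames it averaged.
    Raises ``ValueError`` when no frame is stimulus-free.
    """
    idx = stimulus_free_frames(movie, stim, quiet_margin_s)
    if idx.size == 0:
        raise ValueError("no baseline available: every frame is inside a response window")
    return movie.frames[idx].mean(axis=0), idx


def compute_dff_movie(
    movie: FluorescenceMovie | np.ndarray,
    baseline: np.ndarray,
    baseline_floor: float = 1e-6,
) -> np.ndarray:
    """Pixel-wise fractional change ``(F - F0) / F0``.

    Pixels whose baseline is at or below ``baseline_floor`` are masked to NaN
    rather than producing unbounded ratios; NaNs propagate through ROI
    averaging as missing values.
    """
    frames = movie.frames if isinstance(movie, FluorescenceMovie) else np.asarray(movie, float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != frames.shape[1:]:
        raise ValueError("baseline shape must match frame shape")
    valid = baseline > baseline_floor
    if not valid.any():
        raise ValueError("baseline is zero (or below floor) everywhere")
    safe = np.where(valid, baseline, 1.0)
    dff = (frames - baseline[None]) / safe[None]
    dff[:, ~valid] = np.nan
    return dff


def extract_roi_traces(
    dff: np.ndarray,
    rois: RoiSet,
    frame_rate_hz: float,
    t0_s: float = 0.0,
) -> list[DffTrace]:
    """Unweighted mean over each ROI's pixels, per frame, skipping masked pixels.

    An ROI whose pixels are all masked yields a trace flagged ``valid=False``.
    """
    T, H, W = dff.shape
    time_s = t0_s + np.arange(T) / frame_rate_hz
    traces: list[DffTrace] = []
    for label, mask in rois:
        if mask.shape != (H, W):
            raise ValueError(f"ROI {label!r}: mask shape {mask.shape} != frame {H, W}")
        pix = dff[:, mask]  # (T, n_pix)
        if np.isnan(pix).all():
            traces.append(
                DffTrace(label, time_s, np.full(T, np.nan), valid=False)
            )
            continue
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(pix, axis=1)
        traces.append(DffTrace(label, time_s, vals))
    return traces


def _double_exp(t, c0, a1, tau1, a2, tau2):
    return c0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _single_exp(t, c0, a1, tau1):
    return c0 + a1 * np.exp(-t / tau1)


def correct_photobleach(
    trace: DffTrace,
    stim: StimulusLog | None = None,
    response_window_s: float = 2.0,
    fit_segments_only: bool = True,
) -> DffTrace:
    """Fit and subtract a two-time-constant exponential bleaching trend.

    The model ``c0 + a1 e^(-t/tau1) + a2 e^(-t/tau2)`` is fitted by nonlinear
    least squares to samples outside the stimulus response windows (or to the
    whole trace when ``fit_segments_only`` is False), evaluated on all samples
    and subtracted.  Initialisation is deterministic: c0 from the tail mean,
    a1 = a2 = half the head-minus-tail excursion, tau1/tau2 at 10 % and 60 %
    of the trace duration, with tau bounded to [one frame period, 10x the
    trace duration].  On non-convergence a single exponential and finally a
    straight line are tried; the model actually used is recorded.
    """
    t = trace.time_s
    y = trace.dff
    fit_mask = np.isfinite(y)
    if stim is not None and fit_segments_only:
        for ev in stim:
            fit_mask &= ~((t >= ev.onset_s) & (t < ev.onset_s + response_window_s))
    if not fit_mask.any():
        raise ValueError("all samples fall inside response windows; cannot fit bleach")
    if fit_mask.sum() < 8:
        raise ValueError("need >= 8 samples outside response windows to fit bleach model")

    tf, yf = t[fit_mask], y[fit_mask]
    t_ref = tf[0]
    tf = tf - t_ref  # fit in elapsed time so exp() stays well scaled
    span = max(tf[-1], np.min(np.diff(tf)))
    dt = float(np.min(np.diff(tf)))
    n_head = max(1, tf.size // 10)
    head = float(np.mean(yf[:n_head]))
    tail = float(np.mean(yf[-n_head:]))
    c0_0 = tail
    a0 = 0.5 * max(head - tail, 0.0)
    p0 = [c0_0, a0, 0.1 * span, a0, 0.6 * span]
    lb = [-np.inf, 0.0, dt, 0.0, dt]
    ub = [np.inf, np.inf, 10.0 * span, np.inf, 10.0 * span]

    fit: BleachFit | None = None
    try:
        popt, _ = curve_fit(
            _double_exp, tf, yf, p0=p0, bounds=(lb, ub), maxfev=20000
        )
        resid = yf - _double_exp(tf, *popt)
        c0, a1, tau1, a2, tau2 = popt
        if tau1 > tau2:
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        fit = BleachFit(c0, a1, tau1, a2, tau2, float(resid @ resid))
    except RuntimeError:
        pass
    if fit is None:
        try:
            popt, _ = curve_fit(
                _single_exp, tf, yf, p0=[c0_0, 2 * a0, 0.3 * span],
                bounds=([-np.inf, 0.0, dt], [np.inf, np.inf, 10.0 * span]),
                maxfev=20000,
            )
            resid = yf - _single_exp(tf, *popt)
            fit = BleachFit(
                popt[0], popt[1], popt[2], 0.0, popt[2],
                float(resid @ resid), model="single_exp",
            )
        except RuntimeError:
            slope, intercept = np.polyfit(tf, yf, 1)
            resid = yf - (intercept + slope * tf)
            fit = BleachFit(
                intercept, slope, 1.0, 0.0, 1.0, float(resid @ resid), model="linear"
            )

    corrected = y - fit.predict(t - t_ref)
    return replace(
        trace, dff=corrected, bleach_corrected=True, bleach_fit=fit
    )


def detect_response(
    trace: DffTrace,
    event: StimulusEvent,
    baseline_window_s: float = 2.0,
    response_window_s: float = 2.0,
    criterion_k: float = 2.0,
    event_index: int = 0,
) -> ResponseDetection:
    """Score one pulse against the >k standard-deviation response criterion.

    ``baseline`` spans [onset - baseline_window_s, onset) — i.e. it ends one
    frame before the pulse; ``response`` spans [onset, onset +
    response_window_s).  The response amplitude is the peak of the trace in
    the response window minus the baseline mean, and a response is detected
    when it exceeds ``criterion_k`` times the baseline SD.
    """
    if baseline_window_s <= 0 or response_window_s <= 0:
        raise ValueError("windows must have positive length")
    t = trace.time_s
    base = (t >= event.onset_s - baseline_window_s) & (t < event.onset_s)
    resp = (t >= event.onset_s) & (t < event.onset_s + response_window_s)
    yb = trace.dff[base]
    yb = yb[np.isfinite(yb)]
    yr = trace.dff[resp]
    yr = yr[np.isfinite(yr)]
    if yb.size < 3:
        raise ValueError("baseline window must contain >= 3 samples")
    if yr.size == 0:
        raise ValueError("response window contains no samples")
    baseline_sd = float(np.std(yb, ddof=1))
    response_amp = float(np.max(yr) - np.mean(yb))
    detected = response_amp > criterion_k * baseline_sd
    return ResponseDetection(
        label=trace.label,
        event_index=event_index,
        event=event,
        response_amp=response_amp,
        baseline_sd=baseline_sd,
        detected=bool(detected),
        criterion_k=criterion_k,
    )


def estimate_threshold(
    detections: Sequence[ResponseDetection],
    min_fraction: float = 0.5,
) -> ThresholdEstimate:
    """Activation threshold from per-pulse detections at one pulse duration.

    Repeats at each current are aggregated into a detection fraction; a
    current *qualifies* when its fraction >= ``min_fraction``.  The threshold
    is the lowest tested current such that it and every higher tested current
    qualify (monotone closure: an isolated low-current detection does not set
    the threshold).  Returns ``reached=False`` when no current qualifies.
    """
    if not detections:
        raise ValueError("no detections supplied")
    durations = {d.event.duration_us for d in detections}
    if len(durations) > 1:
        raise ValueError(
            f"mixed pulse durations in one threshold group: {sorted(durations)}"
        )
    currents = np.array(sorted({d.event.current_uA for d in detections}))
    if currents.size < 2:
        raise ValueError("need >= 2 distinct tested currents")
    frac = np.array(
        [
            np.mean([d.detected for d in detections if d.event.current_uA == c])
            for c in currents
        ]
    )
    qualifies = frac >= min_fraction
    threshold = None
    # monotone closure: smallest current with all higher currents qualifying
    for i in range(currents.size):
        if qualifies[i:].all():
            threshold = float(currents[i])
            break
    return ThresholdEstimate(
        label=detections[0].label,
        duration_us=durations.pop(),
        threshold_uA=threshold,
        tested_currents_uA=currents,
        detection_fraction=frac,
        reached=threshold is not None,
        min_fraction=min_fraction,
    )
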