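"""Synthetic optical-recording and ERG data with known ground truth.

The generators emulate the recording conditions this package's analysis
targets — GCaMP6f fluorescence of retinal ganglion cells on a 200 µm-pitch
MEA stimulated at 0.2 Hz with 0.1–1 ms cathodic pulses, imaged at 10 fps,
and in-vivo flash ERGs at 2 Hz — so that every analysis stage can be tested
by parameter recovery against the generating values.

Movie model
-----------
``frame(t,x,y) = F0 · [cells + background] · B(t) · (1 + dff(t,x,y)) + noise``
with double-exponential photobleaching ``B(t) = 1 − a1(1−e^{−t/τ1}) −
a2(1−e^{−t/τ2})`` (so ``B(0)=1``) and, per pulse, a GCaMP-like transient
``(1−e^{−t'/τ_rise})·e^{−t'/τ_decay}`` (peak-normalised) scaled by a
sigmoidal recruitment in current and by a spatial Gaussian footprint centred
on the stimulating electrode.

Recruitment is all-or-none with graded amplitude: a cell produces no
transient when the sigmoid falls below ``firing_gate`` (spikes are
all-or-none events; calcium amplitude then grows with the number of recruited
spikes).  The current at which the sigmoid crosses the gate is the generated
detection boundary and is recorded in the ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .caimg import FluorescenceMovie, StimulusEvent, StimulusLog

__all__ = [
    "CellSpec",
    "MovieSpec",
    "ErgSpec",
    "ErgTraceSet",
    "GroundTruth",
    "generate_movie",
    "generate_erg",
    "generate_sd_points",
    "make_stimulus_ladder",
    "transient_waveform",
    "place_cells",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class CellSpec:
    """A GCaMP-positive soma: position (µm), radius (µm), brightness (× F0)."""

    center_xy_um: tuple[float, float]
    radius_um: float
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.brightness <= 0:
            raise ValueError("brightness must be > 0")


@dataclass
class MovieSpec:
    """Generative description of a fluorescence movie.

    Defaults mirror the targeted recording conditions: 10 fps imaging, a
    30 µm electrode of a 200 µm-pitch MEA at the field centre, 0.2 Hz
    cathodic pulses, GCaMP6f-like kinetics (fast rise, ~0.6 s decay).
    """

    height_px: int = 64
    width_px: int = 64
    um_per_px: float = 2.0
    frame_rate_hz: float = 10.0
    duration_s: float = 60.0
    baseline_f0: float = 1000.0
    background_level: float = 0.2
    noise_sd: float = 0.0
    bleach_a1: float = 0.05
    bleach_tau1_s: float = 5.0
    bleach_a2: float = 0.10
    bleach_tau2_s: float = 60.0
    cells: list[CellSpec] = field(default_factory=list)
    electrode_xy_um: tuple[float, float] | None = None  # None -> field centre
    spot_fwhm_um: float = 60.0
    recruit_i50_uA: float = 25.0
    recruit_slope_uA: float = 2.0
    firing_gate: float = 0.05
    resp_rise_tau_s: float = 0.1
    resp_decay_tau_s: float = 0.6
    resp_peak_dff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bleach_tau1_s", "bleach_tau2_s", "resp_rise_tau_s",
                     "resp_decay_tau_s", "frame_rate_hz", "spot_fwhm_um",
                     "um_per_px", "recruit_slope_uA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bleach_a1 < 0 or self.bleach_a2 < 0:
            raise ValueError("bleach amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.firing_gate < 1.0:
            raise ValueError("firing_gate must be in [0, 1)")
        if self.electrode_xy_um is None:
            self.electrode_xy_um = (
                self.width_px * self.um_per_px / 2.0,
                self.height_px * self.um_per_px / 2.0,
            )

    @property
    def detection_boundary_uA(self) -> float:
        """Current where recruitment crosses the firing gate (the generated
        detection boundary); 0 when the gate is 0 (pure sigmoid)."""
        if self.firing_gate == 0.0:
            return 0.0
        return self.recruit_i50_uA + self.recruit_slope_uA * math.log(
            self.firing_gate / (1.0 - self.firing_gate)
        )


@dataclass
class ErgSpec:
    """Generative description of a flash-ERG recording session.

    Each flash epoch is a negative a-wave lobe, a positive b-wave lobe and a
    Gaussian-windowed oscillatory-potential wavelet riding the b-wave rising
    phase; amplitudes scale as ``(I / I_max)^exponent`` across intensities.
    """

    sampling_rate_hz: float = 2000.0
    duration_s: float = 60.0
    stim_rate_hz: float = 2.0
    intensities_cds_m2: list[float] = field(default_factory=lambda: [0.00978, 1.0, 80.0, 640.0])
    a_amp_uv: float = 50.0
    b_amp_uv: float = 120.0
    op_freq_hz: float = 120.0
    op_amp_uv: float = 20.0
    amp_vs_intensity_exponent: float = 0.25
    noise_sd_uv: float = 0.0
    a_peak_s: float = 0.020
    a_sigma_s: float = 0.005
    b_peak_s: float = 0.060
    b_sigma_s: float = 0.012
    op_center_s: float = 0.045
    op_sigma_s: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 1000:
            raise ValueError("sampling_rate_hz must be >= 1000 to resolve 160 Hz OPs")
        for name in ("a_amp_uv", "b_amp_uv", "op_amp_uv", "noise_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.intensities_cds_m2:
            raise ValueError("need at least one stimulus intensity")


@dataclass
class GroundTruth:
    """Sidecar truth record so tests never re-derive truth from the data."""

    spot_fwhm_um: float | None = None
    detection_boundary_uA: float | None = None
    threshold_uA_by_duration: dict[str, float] | None = None
    transient_peak_dff: float | None = None
    bleach: dict[str, float] | None = None
    rheobase_uA: float | None = None
    chronaxie_ms: float | None = None
    erg_amplitude_uv_by_intensity: dict[str, float] | None = None
    op_amplitude_uv_by_intensity: dict[str, float] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {k: v for k, v in asdict(self).items() if v is not None}, indent=2
        )


@dataclass
class ErgTraceSet:
    """Generated ERG voltage records, one per stimulus intensity."""

    traces: dict[float, "np.ndarray"]  # intensity -> voltage (µV)
    time_s: np.ndarray
    sampling_rate_hz: float
    stim_onsets_s: np.ndarray


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def transient_waveform(
    t: np.ndarray, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Peak-normalised GCaMP-like transient ``(1−e^{−t/τr})·e^{−t/τd}`` for t>=0."""
    t = np.asarray(t, dtype=float)
    a, b = rise_tau_s, decay_tau_s
    t_peak = a * math.log((a + b) / a)  # stationary point of the product
    peak = (1.0 - math.exp(-t_peak / a)) * math.exp(-t_peak / b)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (1.0 - np.exp(-t[pos] / a)) * np.exp(-t[pos] / b) / peak
    return out


def recruitment(current_uA: np.ndarray | float, i50: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(current_uA, float) - i50) / slope))


def bleach_curve(t: np.ndarray, a1: float, tau1: float, a2: float, tau2: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return 1.0 - a1 * (1.0 - np.exp(-t / tau1)) - a2 * (1.0 - np.exp(-t / tau2))


def make_stimulus_ladder(
    currents_uA: Sequence[float],
    n_reps: int = 1,
    duration_us: float = 100.0,
    rate_hz: float = 0.2,
    start_s: float = 10.0,
    electrode_id: int = 0,
) -> StimulusLog:
    """Ascending current ladder, ``n_reps`` pulses per current at ``rate_hz``."""
    events = []
    t = start_s
    for c in sorted(currents_uA):
        for _ in range(n_reps):
            events.append(
                StimulusEvent(t, float(c), float(duration_us), electrode_id=electrode_id)
            )
            t += 1.0 / rate_hz
    return StimulusLog(events)


def place_cells(
    spec: MovieSpec,
    n_cells: int,
    radius_um: float = 8.0,
    min_dist_um: float = 30.0,
    brightness: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[CellSpec]:
    """Uniform random somata with minimum-distance rejection sampling."""
    rng = rng or np.random.default_rng(spec.seed)
    w_um = spec.width_px * spec.um_per_px
    h_um = spec.height_px * spec.um_per_px
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n_cells and attempts < 10000:
        attempts += 1
        x = rng.uniform(radius_um, w_um - radius_um)
        y = rng.uniform(radius_um, h_um - radius_um)
        if all(math.hypot(x - px, y - py) >= min_dist_um for px, py in placed):
            placed.append((x, y))
    if len(placed) < n_cells:
        raise ValueError("could not place cells with requested minimum distance")
    return [CellSpec((x, y), radius_um, brightness) for x, y in placed]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _static_image(spec: MovieSpec) -> np.ndarray:
    """Unbleached base image: background plus cell disks, in units of F0."""
    H, W = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:H, 0:W]
    x_um = (xx + 0.5) * spec.um_per_px
    y_um = (yy + 0.5) * spec.um_per_px
    img = np.full((H, W), spec.background_level, dtype=float)
    for cell in spec.cells:
        cx, cy = cell.center_xy_um
        disk = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= cell.radius_um**2
        img[disk] += cell.brightness
    return img


def generate_movie(
    spec: MovieSpec, stim: StimulusLog
) -> tuple[FluorescenceMovie, GroundTruth]:
    """Render a fluorescence movie for a stimulus log; returns stack + truth.

    Reproducible given ``spec.seed``.  Rejects stimuli outside the record and
    footprints narrower than 2 pixels (unresolvable).
    """
    if spec.spot_fwhm_um < 2.0 * spec.um_per_px:
        raise ValueError("spot FWHM below 2 pixels is unresolvable")
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    if n_frames < 2:
        raise ValueError("movie duration too short")
    t = np.arange(n_frames) / spec.frame_rate_hz
    for ev in stim:
        if not (0.0 <= ev.onset_s < spec.duration_s):
            raise ValueError(
                f"stimulus onset {ev.onset_s} s outside [0, {spec.duration_s}) s"
            )

    H, W = spec.height_px, spec.width_px
    base = spec.baseline_f0 * _static_image(spec)
    B = bleach_curve(t, spec.bleach_a1, spec.bleach_tau1_s,
                     spec.bleach_a2, spec.bleach_tau2_s)

    # spatial activation footprint centred on the electrode
    yy, xx = np.mgrid[0:H, 0:W]
    x_um = (xx + 0.5) * spec.um_per_px
    y_um = (yy + 0.5) * spec.um_per_px
    ex, ey = spec.electrode_xy_um
    sigma_um = spec.spot_fwhm_um / FWHM_PER_SIGMA
    footprint = np.exp(
        -((x_um - ex) ** 2 + (y_um - ey) ** 2) / (2.0 * sigma_um**2)
    )

    # temporal dF/F at the footprint centre: sum of gated, recruited transients
    g_total = np.zeros(n_frames)
    for ev in stim:
        r = float(recruitment(ev.current_uA, spec.recruit_i50_uA, spec.recruit_slope_uA))
        if r < spec.firing_gate:
            continue
        g_total += (
            spec.resp_peak_dff
            * r
            * transient_waveform(t - ev.onset_s, spec.resp_rise_tau_s, spec.resp_decay_tau_s)
        )

    dff = g_total[:, None, None] * footprint[None, :, :]
    frames = base[None, :, :] * B[:, None, None] * (1.0 + dff)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    movie = FluorescenceMovie(frames, spec.frame_rate_hz, spec.um_per_px)
    durations = sorted({ev.duration_us for ev in stim})
    currents = sorted({ev.current_uA for ev in stim})
    boundary = spec.detection_boundary_uA
    thr_by_dur = {}
    for d in durations:
        above = [c for c in currents if c >= boundary]
        thr_by_dur[str(d)] = float(min(above)) if above else float("nan")
    truth = GroundTruth(
        spot_fwhm_um=spec.spot_fwhm_um,
        detection_boundary_uA=boundary,
        threshold_uA_by_duration=thr_by_dur or None,
        transient_peak_dff=spec.resp_peak_dff,
        bleach=dict(
            a1=spec.bleach_a1, tau1_s=spec.bleach_tau1_s,
            a2=spec.bleach_a2, tau2_s=spec.bleach_tau2_s,
        ),
    )
    return movie, truth


def erg_epoch_waveform(spec: ErgSpec, t: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Noise-free epoch waveform (µV) at post-flash times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    wave = (
        -spec.a_amp_uv * np.exp(-((t - spec.a_peak_s) ** 2) / (2 * spec.a_sigma_s**2))
        + spec.b_amp_uv * np.exp(-((t - spec.b_peak_s) ** 2) / (2 * spec.b_sigma_s**2))
        + spec.op_amp_uv
        * np.exp(-((t - spec.op_center_s) ** 2) / (2 * spec.op_sigma_s**2))
        * np.sin(2 * np.pi * spec.op_freq_hz * (t - spec.op_center_s))
    )
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = scale * wave[pos]
    return out


def generate_erg(spec: ErgSpec) -> tuple[ErgTraceSet, GroundTruth]:
    """Render one ≥60 s voltage record per intensity; returns traces + truth.

    Amplitudes scale as ``(I/I_max)^exponent``; flashes at ``stim_rate_hz``.
    """
    if spec.duration_s < 60:
        raise ValueError("ERG records must span >= 60 s")
    if spec.sampling_rate_hz < 2 * 160:
        raise ValueError("sampling rate cannot represent the 80-160 Hz OP band")
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    period = 1.0 / spec.stim_rate_hz
    onsets = np.arange(period / 2.0, spec.duration_s - 1e-9, period)
    i_ref = max(spec.intensities_cds_m2)
    rng = np.random.default_rng(spec.seed)

    traces: dict[float, np.ndarray] = {}
    amp_truth: dict[str, float] = {}
    op_truth: dict[str, float] = {}
    for inten in spec.intensities_cds_m2:
        scale = (inten / i_ref) ** spec.amp_vs_intensity_exponent
        v = np.zeros(n)
        for onset in onsets:
            v += erg_epoch_waveform(spec, t - onset, scale)
        if spec.noise_sd_uv > 0:
            v = v + rng.normal(0.0, spec.noise_sd_uv, size=n)
        traces[float(inten)] = v
        amp_truth[str(inten)] = scale * (spec.a_amp_uv + spec.b_amp_uv)
        op_truth[str(inten)] = scale * 2.0 * spec.op_amp_uv
    truth = GroundTruth(
        erg_amplitude_uv_by_intensity=amp_truth,
        op_amplitude_uv_by_intensity=op_truth,
    )
    return ErgTraceSet(traces, t, fs, onsets), truth


def generate_sd_points(
    rheobase_uA: float,
    chronaxie_ms: float,
    durations_ms: Sequence[float] = (0.1, 0.2, 0.5, 1.0),
    noise_cv: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Strength–duration threshold samples from the hyperbolic (Lapicque) law.

    ``threshold(d) = rheobase · (1 + chronaxie/d)`` perturbed by multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` (mean 1).
    """
    if any(d <= 0 for d in durations_ms):
        raise ValueError("pulse durations must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    points: list[tuple[float, float]] = []
    for d in durations_ms:
        ideal = rheobase_uA * (1.0 + chronaxie_ms / d)
        for _ in range(n_reps):
            if sigma > 0:
                factor = math.exp(rng.normal(-0.5 * sigma**2, sigma))
            else:
                factor = 1.0
            points.append((float(d), float(ideal * factor)))
    return points
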