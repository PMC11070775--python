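"""End-to-end analysis pipeline: dF/F -> bleach correction -> detection ->
thresholds -> z maps -> spread -> strength-duration fit.

A :class:`PipelineConfig` is validated before any stage runs; every run
writes its artefacts into a fresh directory together with a structured log
(config hash, package version, per-stage status).  Stage failures are
recorded and dependent stages are skipped, but the partial bundle is still
written.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .caimg import (
    FluorescenceMovie,
    RoiSet,
    StimulusLog,
    compute_baseline_frame,
    compute_dff_movie,
    correct_photobleach,
    detect_response,
    estimate_threshold,
    extract_roi_traces,
)
from .sdcurve import fit_lapicque
from .spatial import compute_zscore_map, fit_gaussian2d, spread_diameter

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated settings for one pipeline invocation."""

    baseline_window_s: float = Field(2.0, gt=0)
    response_window_s: float = Field(2.0, gt=0)
    quiet_margin_s: float = Field(2.0, gt=0)
    criterion_k: float = Field(2.0, gt=0)
    min_fraction: float = Field(0.5, ge=0, le=1)
    z_threshold: float = Field(2.0, gt=0)
    sd_floor: float = Field(1e-4, gt=0)
    baseline_floor: float = Field(1e-6, gt=0)
    bleach_correction: bool = True
    sd_model: str = "lapicque"
    band_low_hz: float = Field(80.0, gt=0)
    band_high_hz: float = Field(160.0, gt=0)
    um_per_px: float | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check_band(self):
        if self.band_high_hz <= self.band_low_hz:
            raise ValueError("band_high_hz must exceed band_low_hz")
        if self.sd_model not in ("lapicque", "weiss"):
            raise ValueError("sd_model must be 'lapicque' or 'weiss'")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_against_stimuli(config: PipelineConfig, stim: StimulusLog) -> None:
    """Reject configs whose response window overlaps the next pulse."""
    onsets = stim.onsets_s
    if onsets.size >= 2:
        min_ipi = float(np.min(np.diff(onsets)))
        if config.response_window_s > min_ipi:
            raise ValueError(
                f"response window {config.response_window_s} s overlaps the next "
                f"pulse (minimum inter-pulse interval {min_ipi} s)"
            )


def run_pipeline(
    config: PipelineConfig,
    movie: FluorescenceMovie,
    stim: StimulusLog,
    rois: RoiSet,
    outdir: str | Path,
) -> dict:
    """Execute every stage in order, writing artefacts to ``outdir``.

    Returns the report bundle: per-stage status plus in-memory results.
    Numeric outputs are deterministic for a fixed config and inputs.
    """
    validate_against_stimuli(config, stim)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=False)
    chash = config.config_hash()
    stages: dict[str, str] = {}
    bundle: dict = {"stages": stages, "config_hash": chash}

    um_per_px = config.um_per_px or movie.um_per_px

    def _write_df(df: pd.DataFrame, name: str) -> None:
        df.insert(0, "config_hash", chash)
        df.to_csv(outdir / name, index=False)

    # --- dF/F ---------------------------------------------------------------
    try:
        baseline, base_idx = compute_baseline_frame(movie, stim, config.quiet_margin_s)
        dff = compute_dff_movie(movie, baseline, config.baseline_floor)
        traces = extract_roi_traces(dff, rois, movie.frame_rate_hz, movie.t0_s)
        raw = {t.label: t for t in traces}
        if config.bleach_correction:
            traces = [
                correct_photobleach(t, stim, config.response_window_s)
                if t.valid else t
                for t in traces
            ]
        rows = []
        for t in traces:
            for i in range(t.time_s.size):
                rows.append((t.label, t.time_s[i], raw[t.label].dff[i], t.dff[i]))
        _write_df(
            pd.DataFrame(rows, columns=["roi", "time_s", "dff_raw", "dff_corrected"]),
            "traces.csv",
        )
        stages["dff"] = "ok"
    except Exception as exc:  # noqa: BLE001 - failure is part of the report
        stages["dff"] = f"failed: {exc}"
        _finish(bundle, outdir, config)
        return bundle

    # --- detection + thresholds --------------------------------------------
    try:
        det_rows = []
        detections = {t.label: [] for t in traces if t.valid}
        for t in traces:
            if not t.valid:
                continue
            for i, ev in enumerate(stim):
                det = detect_response(
                    t, ev, config.baseline_window_s, config.response_window_s,
                    config.criterion_k, event_index=i,
                )
                detections[t.label].append(det)
                det_rows.append((t.label, i, ev.onset_s, ev.current_uA,
                                 ev.duration_us, det.response_amp,
                                 det.baseline_sd, det.detected))
        _write_df(
            pd.DataFrame(det_rows, columns=[
                "roi", "event", "onset_s", "current_uA", "duration_us",
                "response_amp", "baseline_sd", "detected"]),
            "detections.csv",
        )
        thr_rows = []
        thresholds = []
        for label, dets in detections.items():
            for dur in sorted({d.event.duration_us for d in dets}):
                sub = [d for d in dets if d.event.duration_us == dur]
                if len({d.event.current_uA for d in sub}) < 2:
                    continue
                est = estimate_threshold(sub, config.min_fraction)
                thresholds.append(est)
                thr_rows.append((label, dur, est.threshold_uA, est.reached))
        _write_df(
            pd.DataFrame(thr_rows, columns=["roi", "duration_us", "threshold_uA",
                                            "reached"]),
            "thresholds.csv",
        )
        bundle["thresholds"] = thresholds
        stages["threshold"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["threshold"] = f"failed: {exc}"
        thresholds = []

    # --- z maps + spread ----------------------------------------------------
    try:
        spread_rows = []
        zmaps = []
        for i, ev in enumerate(stim):
            zmap = compute_zscore_map(
                dff, base_idx, ev, movie.frame_rate_hz,
                config.response_window_s, config.sd_floor, movie.t0_s,
            )
            zmaps.append(zmap.z.astype(np.float32))
            fit = fit_gaussian2d(zmap, config.z_threshold)
            if fit.valid and fit.converged:
                est = spread_diameter(fit, um_per_px)
                spread_rows.append((i, ev.current_uA, ev.duration_us,
                                    est.diameter_um, est.fwhm_x_um, est.fwhm_y_um))
            else:
                spread_rows.append((i, ev.current_uA, ev.duration_us,
                                    np.nan, np.nan, np.nan))
        tifffile.imwrite(outdir / "zmaps.tif", np.stack(zmaps),
                         photometric="minisblack")
        _write_df(
            pd.DataFrame(spread_rows, columns=[
                "event", "current_uA", "duration_us", "diameter_um",
                "fwhm_x_um", "fwhm_y_um"]),
            "spread.csv",
        )
        stages["spread"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["spread"] = f"failed: {exc}"

    # --- strength-duration fit ---------------------------------------------
    try:
        points = [
            (est.duration_us / 1000.0, est.threshold_uA)
            for est in thresholds
            if est.reached
        ]
        if len({p[0] for p in points}) >= 2:
            res = fit_lapicque(points, model=config.sd_model)
            (outdir / "sdcurve.json").write_text(json.dumps({
                "config_hash": chash,
                "model": res.model,
                "rheobase_uA": res.rheobase_uA,
                "chronaxie_ms": res.chronaxie_ms,
                "rss": res.rss,
                "n_points": res.n_points,
            }, indent=2))
            bundle["sdcurve"] = res
            stages["sdcurve"] = "ok"
        else:
            stages["sdcurve"] = "skipped: fewer than 2 pulse durations with thresholds"
    except Exception as exc:  # noqa: BLE001
        stages["sdcurve"] = f"failed: {exc}"

    _finish(bundle, outdir, config)
    return bundle


def _finish(bundle: dict, outdir: Path, config: PipelineConfig) -> None:
    (outdir / "run_log.json").write_text(json.dumps({
        "package": "retistim",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.model_dump(),
        "config_hash": bundle["config_hash"],
        "stages": bundle["stages"],
    }, indent=2))
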