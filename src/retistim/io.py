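"""Readers and writers for movies, stimulus logs, ROI masks, ERG records, MEA layouts.

Conventions: pixel indices are 0-based row-major with origin at the image
top-left; physical coordinates are micrometres from the same origin; all
times are seconds on the movie clock.  Movies are multi-page single-channel
TIFFs with a JSON sidecar (``<stem>.json``) carrying frame rate, calibration
and, for synthetic data, the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .caimg import FluorescenceMovie, RoiSet, StimulusEvent, StimulusLog
from .erg import ErgTrace

__all__ = [
    "MeaLayout",
    "default_mea_layout",
    "read_movie",
    "write_movie",
    "read_stimulus_log",
    "write_stimulus_log",
    "read_erg_trace",
    "write_erg_trace",
    "rois_from_labeled_image",
    "rois_from_polygons",
    "read_rois",
]


@dataclass
class MeaLayout:
    """Electrode grid geometry (µm): ids, centres, diameter, pitch."""

    electrode_ids: list[int]
    centers_um: list[tuple[float, float]]
    diameter_um: float = 30.0
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        if len(self.electrode_ids) != len(self.centers_um):
            raise ValueError("one centre per electrode id required")
        if len({tuple(c) for c in self.centers_um}) != len(self.centers_um):
            raise ValueError("electrode positions must be unique")
        if not self.diameter_um < self.pitch_um:
            raise ValueError("electrode diameter must be smaller than the pitch")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "electrode_ids": self.electrode_ids,
            "centers_um": [list(c) for c in self.centers_um],
            "diameter_um": self.diameter_um,
            "pitch_um": self.pitch_um,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MeaLayout":
        d = json.loads(Path(path).read_text())
        return cls(
            electrode_ids=list(d["electrode_ids"]),
            centers_um=[tuple(c) for c in d["centers_um"]],
            diameter_um=float(d.get("diameter_um", 30.0)),
            pitch_um=float(d.get("pitch_um", 200.0)),
        )


def default_mea_layout() -> MeaLayout:
    """60-electrode grid: 8x8 at 200 µm pitch minus the four corners,
    30 µm electrodes."""
    ids, centers = [], []
    k = 0
    for row in range(8):
        for col in range(8):
            if (row, col) in {(0, 0), (0, 7), (7, 0), (7, 7)}:
                continue
            ids.append(k)
            centers.append((col * 200.0, row * 200.0))
            k += 1
    return MeaLayout(ids, centers)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(path: str | Path, movie: FluorescenceMovie,
                sidecar: dict | None = None, dtype: str = "uint16") -> None:
    """Write a multi-page grayscale TIFF plus JSON sidecar.

    ``dtype='uint16'`` rounds and clips to the camera-like 16-bit range;
    ``dtype='float32'`` preserves values exactly.
    """
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = movie.frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "um_per_px": movie.um_per_px,
        "t0_s": movie.t0_s,
    }
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_movie(path: str | Path, frame_rate_hz: float | None = None,
               um_per_px: float | None = None) -> FluorescenceMovie:
    """Load a single-channel multi-page TIFF; metadata from sidecar or flags.

    RGB / multi-channel TIFFs are rejected.  Frame rate must come from the
    JSON sidecar or the ``frame_rate_hz`` argument; absence is an error.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {stack.shape}: expected a single-channel "
            "multi-page stack (multi-channel/RGB is not supported)"
        )
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if rate is None:
        raise ValueError("frame rate unavailable: provide a sidecar or frame_rate_hz")
    scale = um_per_px if um_per_px is not None else meta.get("um_per_px", 1.0)
    return FluorescenceMovie(stack.astype(float), float(rate), float(scale),
                             t0_s=float(meta.get("t0_s", 0.0)))


# ---------------------------------------------------------------------------
# stimulus logs
# ---------------------------------------------------------------------------

_STIM_COLUMNS = ["onset_s", "current_uA", "duration_us", "polarity", "electrode_id"]


def write_stimulus_log(path: str | Path, stim: StimulusLog) -> None:
    pd.DataFrame(
        [(e.onset_s, e.current_uA, e.duration_us, e.polarity, e.electrode_id)
         for e in stim],
        columns=_STIM_COLUMNS,
    ).to_csv(path, index=False)


def read_stimulus_log(path: str | Path) -> StimulusLog:
    df = pd.read_csv(path)
    missing = set(_STIM_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"stimulus log missing columns: {sorted(missing)}")
    events = [
        StimulusEvent(
            float(r.onset_s), float(r.current_uA), float(r.duration_us),
            str(getattr(r, "polarity", "cathodic")),
            int(getattr(r, "electrode_id", 0)),
        )
        for r in df.itertuples()
    ]
    return StimulusLog(events)


# ---------------------------------------------------------------------------
# ERG records
# ---------------------------------------------------------------------------


def write_erg_trace(path: str | Path, trace: ErgTrace) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "voltage_uv": trace.voltage_uv}
                 ).to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps({
        "sampling_rate_hz": trace.sampling_rate_hz,
        "stim_onsets_s": list(map(float, trace.stim_onsets_s)),
        "intensity_cds_m2": trace.intensity_cds_m2,
    }, indent=2))


def read_erg_trace(path: str | Path) -> ErgTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return ErgTrace(
        df["time_s"].to_numpy(), df["voltage_uv"].to_numpy(),
        float(meta["sampling_rate_hz"]), np.asarray(meta["stim_onsets_s"]),
        float(meta["intensity_cds_m2"]),
    )


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------


def rois_from_labeled_image(labels: np.ndarray) -> RoiSet:
    """Each positive integer label becomes one ROI mask."""
    labels = np.asarray(labels)
    rois = [(str(v), labels == v) for v in np.unique(labels) if v > 0]
    if not rois:
        raise ValueError("labeled image contains no positive labels")
    return RoiSet(rois)


def rois_from_polygons(polygons: list[dict], shape: tuple[int, int]) -> RoiSet:
    """Rasterise ``[{"label": ..., "vertices_px": [[x, y], ...]}, ...]``."""
    from skimage.draw import polygon as sk_polygon

    rois = []
    for spec in polygons:
        verts = np.asarray(spec["vertices_px"], dtype=float)
        rr, cc = sk_polygon(verts[:, 1], verts[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        rois.append((str(spec.get("label", len(rois))), mask))
    return RoiSet(rois)


def read_rois(path: str | Path, shape: tuple[int, int] | None = None) -> RoiSet:
    """Load ROIs from a labeled TIFF/PNG or a JSON polygon list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise ValueError("frame shape required to rasterise polygon ROIs")
        return rois_from_polygons(json.loads(path.read_text()), shape)
    if path.suffix.lower() in (".tif", ".tiff"):
        return rois_from_labeled_image(tifffile.imread(path))
    from imageio.v3 import imread

    return rois_from_labeled_image(imread(path))
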