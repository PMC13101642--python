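"""File formats: multi-page float TIFF stacks with JSON sidecar metadata,
ground-truth JSON, label TIFFs, and CSV/JSON analysis artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import FrameStack, GroundTruth
from .roughness import RoughnessSeries
from .segmentation import CellTrack, LabelMap

__all__ = [
    "StackLoadError",
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_labels",
    "tracks_to_frame",
    "series_to_frame",
]

METADATA_FIELDS = ("pixel_pitch_um", "frame_interval_min", "wavelength_nm")


class StackLoadError(ValueError):
    """Raised when a stack or its metadata fails validation on load."""


def _sidecar_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".json")


def write_stack(stack: FrameStack, tif_path: str | Path) -> tuple[Path, Path]:
    """Write a stack as 32-bit float multi-page TIFF (page order = time
    order) plus an adjacent JSON metadata sidecar."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, stack.data.astype(np.float32))
    meta = {
        "pixel_pitch_um": stack.pixel_pitch_um,
        "frame_interval_min": stack.frame_interval_min,
        "wavelength_nm": stack.wavelength_nm,
        "n_frames": stack.n_frames,
    }
    meta_path = _sidecar_path(tif_path)
    meta_path.write_text(json.dumps(meta, indent=2))
    return tif_path, meta_path


def read_stack(
    tif_path: str | Path, meta_path: str | Path | None = None
) -> FrameStack:
    """Load and strictly validate a stack written by :func:`write_stack`.

    Errors name the offending page or metadata field.
    """
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(tif_path)
    if not meta_path.exists():
        raise StackLoadError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in METADATA_FIELDS:
        if key not in meta:
            raise StackLoadError(f"metadata field {key!r} missing in {meta_path}")

    with tifffile.TiffFile(tif_path) as tf:
        shapes = [p.shape for p in tf.pages]
        ref = shapes[0]
        for i, s in enumerate(shapes):
            if s != ref:
                raise StackLoadError(
                    f"page {i} shape {s} differs from page 0 shape {ref}"
                )
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    for i in range(data.shape[0]):
        if not np.all(np.isfinite(data[i])):
            raise StackLoadError(f"page {i} contains non-finite pixels")
    interval = float(meta["frame_interval_min"])
    return FrameStack(
        data=data,
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
        frame_interval_min=interval,
        timestamps_min=np.arange(data.shape[0]) * interval,
        wavelength_nm=float(meta["wavelength_nm"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_labels(label_maps: list[LabelMap], path: str | Path) -> Path:
    """Export label maps as a 16-bit unsigned multi-page TIFF."""
    path = Path(path)
    arr = np.stack([lm.labels for lm in label_maps]).astype(np.uint16)
    tifffile.imwrite(path, arr)
    return path


def tracks_to_frame(
    tracks: list[CellTrack], frame_interval_min: float
) -> pd.DataFrame:
    """Flatten tracks to a tidy table with deterministic row order."""
    rows = []
    for tr in sorted(tracks, key=lambda t: t.track_id):
        for frame in sorted(tr.observations):
            obs = tr.observations[frame]
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frame,
                    "time_min": frame * frame_interval_min,
                    "label": obs.label,
                    "centroid_row": obs.centroid_rc[0],
                    "centroid_col": obs.centroid_rc[1],
                    "area_px": obs.area_px,
                    "mean_opl_nm": obs.mean_opl_nm,
                    "death_flag": tr.death_flag,
                }
            )
    columns = [
        "track_id", "frame", "time_min", "label", "centroid_row",
        "centroid_col", "area_px", "mean_opl_nm", "death_flag",
    ]
    return pd.DataFrame(rows, columns=columns)


def series_to_frame(series_list: list[RoughnessSeries]) -> pd.DataFrame:
    """Per-cell roughness series as a tidy table (full precision)."""
    rows = []
    for s in sorted(series_list, key=lambda s: s.track_id):
        for i, t in enumerate(s.times_min):
            rows.append(
                {
                    "track_id": s.track_id,
                    "frame": i,
                    "time_min": float(t),
                    "n_px": int(s.n_px[i]),
                    "rq_nm": float(s.rq[i]),
                    "rsk": float(s.rsk[i]),
                    "rku": float(s.rku[i]),
                    "valid": bool(s.valid[i]),
                }
            )
    columns = ["track_id", "frame", "time_min", "n_px", "rq_nm", "rsk", "rku", "valid"]
    return pd.DataFrame(rows, columns=columns)
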