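"""Cell segmentation of OPL frames and frame-to-frame track linking.

Segmentation thresholds each frame with an automatic method chosen for
background-dominated OPL histograms, cleans up small objects and holes, and
optionally splits touching cells by distance-transform watershed.  Tracking
links region centroids greedily between consecutive frames (cells are
near-stationary at one frame per minute), tolerating short gaps.  A simple
collapse detector flags cell death when region area or mean OPL falls
persistently below a fraction of its initial level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation as sk_seg

__all__ = [
    "SegmentationParams",
    "RegionSummary",
    "LabelMap",
    "Observation",
    "CellTrack",
    "segment_frame",
    "track_cells",
    "flag_death",
]

THRESHOLD_METHODS = ("triangle", "otsu", "li", "mad")


@dataclass(frozen=True)
class SegmentationParams:
    threshold_method: str = "mad"
    smooth_sigma_px: float = 1.5  # pre-threshold smoothing; 0 disables
    min_area_px: int = 50
    fill_holes: bool = True
    split_touching: bool = False
    max_link_distance_px: float = 15.0
    max_gap_frames: int = 2
    # death-flag settings
    death_fraction: float = 0.5
    death_min_run: int = 2
    death_init_window: int = 5

    def __post_init__(self):
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(
                f"threshold_method must be one of {THRESHOLD_METHODS}"
            )
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.max_link_distance_px <= 0:
            raise ValueError("max_link_distance_px must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not 0 < self.death_fraction < 1:
            raise ValueError("death_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RegionSummary:
    label: int
    area_px: int
    centroid_rc: tuple[float, float]
    mean_opl_nm: float
    max_opl_nm: float


@dataclass
class LabelMap:
    """Integer label image (0 = background) with per-label summaries."""

    labels: np.ndarray
    regions: list[RegionSummary]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def pixels_of(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.nonzero(self.labels == label)
        return rows, cols


def _auto_threshold(frame: np.ndarray, method: str) -> float:
    if method == "mad":
        # robust background threshold with a foreground-scaled floor: five
        # robust sigmas above the background, but never below 6% of the
        # (robust) foreground height, so near-noiseless frames are not
        # segmented at the smoothing tail of the cell domes
        med = float(np.median(frame))
        mad = float(np.median(np.abs(frame - med)))
        floor = 0.06 * (float(np.percentile(frame, 99.5)) - med)
        return med + max(5.0 * 1.4826 * mad, floor)
    fn = {
        "triangle": filters.threshold_triangle,
        "otsu": filters.threshold_otsu,
        "li": filters.threshold_li,
    }[method]
    return float(fn(frame))


def segment_frame(
    frame: np.ndarray, params: SegmentationParams | None = None
) -> LabelMap:
    """Segment one OPL frame into labelled cell regions.

    Deterministic for fixed input and parameters.  A frame with no
    foreground (e.g. all zeros, or threshold failure on a constant image)
    yields an empty :class:`LabelMap`, not an error.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D array")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")

    if np.ptp(frame) == 0:
        return LabelMap(labels=np.zeros(frame.shape, dtype=np.int32), regions=[])

    # threshold on a lightly smoothed copy (suppresses background shot
    # noise); per-label intensity summaries always use the raw frame
    work = (
        ndi.gaussian_filter(frame, params.smooth_sigma_px)
        if params.smooth_sigma_px > 0
        else frame
    )
    thresh = _auto_threshold(work, params.threshold_method)
    binary = work > thresh
    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)
    # regions below min_area are dropped after labelling

    if not binary.any():
        return LabelMap(labels=np.zeros(frame.shape, dtype=np.int32), regions=[])

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        min_dist = max(3, int(round(math.sqrt(params.min_area_px))))
        coords = morphology.local_maxima(
            ndi.gaussian_filter(distance, 2.0), allow_borders=False
        )
        markers, _ = ndi.label(coords & (distance > min_dist))
        if markers.max() > 0:
            labels = sk_seg.watershed(-distance, markers, mask=binary)
        else:
            labels = measure.label(binary)
    else:
        labels = measure.label(binary)

    # drop any watershed fragments below min_area and relabel sequentially
    regions_raw = measure.regionprops(labels, intensity_image=frame)
    keep = [r for r in regions_raw if r.area >= params.min_area_px]
    out = np.zeros(frame.shape, dtype=np.int32)
    regions: list[RegionSummary] = []
    for new_label, r in enumerate(sorted(keep, key=lambda r: r.label), start=1):
        out[tuple(r.coords.T)] = new_label
        regions.append(
            RegionSummary(
                label=new_label,
                area_px=int(r.area),
                centroid_rc=(float(r.centroid[0]), float(r.centroid[1])),
                mean_opl_nm=float(r.intensity_mean),
                max_opl_nm=float(r.intensity_max),
            )
        )
    return LabelMap(labels=out, regions=regions)


# ---------------------------------------------------------------------------
# tracking


@dataclass
class Observation:
    label: int
    centroid_rc: tuple[float, float]
    area_px: int
    mean_opl_nm: float
    pixels: tuple[np.ndarray, np.ndarray]


@dataclass
class CellTrack:
    """One cell's region identity across the movie."""

    track_id: int
    observations: dict[int, Observation] = field(default_factory=dict)
    death_flag: bool = False
    death_frame: int | None = None

    @property
    def first_frame(self) -> int:
        return min(self.observations)

    @property
    def last_frame(self) -> int:
        return max(self.observations)

    @property
    def n_frames(self) -> int:
        return len(self.observations)

    def series(self, attr: str) -> tuple[np.ndarray, np.ndarray]:
        frames = np.array(sorted(self.observations))
        vals = np.array([getattr(self.observations[f], attr) for f in frames])
        return frames, vals


def track_cells(
    label_maps: list[LabelMap], params: SegmentationParams | None = None
) -> list[CellTrack]:
    """Greedy nearest-centroid linking of regions across frames.

    Matches are made in order of increasing centroid distance subject to
    ``max_link_distance_px``; unmatched tracks survive ``max_gap_frames``
    missed frames before closing; unmatched regions open new tracks.  Track
    ids are assigned by first appearance, then by centroid (row, col).
    """
    params = params or SegmentationParams()
    if not label_maps:
        raise ValueError("need at least one frame")

    tracks: list[CellTrack] = []
    # open track state: (track, last centroid, frames since last match)
    active: list[dict] = []

    for frame_idx, lmap in enumerate(label_maps):
        regions = list(lmap.regions)
        pairs = []
        for ai, st in enumerate(active):
            cr, cc = st["centroid"]
            for ri, reg in enumerate(regions):
                d = math.hypot(cr - reg.centroid_rc[0], cc - reg.centroid_rc[1])
                if d <= params.max_link_distance_px:
                    pairs.append((d, ai, ri))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_a: set[int] = set()
        used_r: set[int] = set()
        for d, ai, ri in pairs:
            if ai in used_a or ri in used_r:
                continue
            used_a.add(ai)
            used_r.add(ri)
            reg = regions[ri]
            st = active[ai]
            st["track"].observations[frame_idx] = Observation(
                label=reg.label,
                centroid_rc=reg.centroid_rc,
                area_px=reg.area_px,
                mean_opl_nm=reg.mean_opl_nm,
                pixels=lmap.pixels_of(reg.label),
            )
            st["centroid"] = reg.centroid_rc
            st["missed"] = 0

        still_active = []
        for ai, st in enumerate(active):
            if ai in used_a:
                still_active.append(st)
            else:
                st["missed"] += 1
                if st["missed"] <= params.max_gap_frames:
                    still_active.append(st)
        active = still_active

        new_regions = sorted(
            (reg for ri, reg in enumerate(regions) if ri not in used_r),
            key=lambda reg: reg.centroid_rc,
        )
        for reg in new_regions:
            track = CellTrack(track_id=len(tracks))
            track.observations[frame_idx] = Observation(
                label=reg.label,
                centroid_rc=reg.centroid_rc,
                area_px=reg.area_px,
                mean_opl_nm=reg.mean_opl_nm,
                pixels=lmap.pixels_of(reg.label),
            )
            tracks.append(track)
            active.append({"track": track, "centroid": reg.centroid_rc, "missed": 0})

    return tracks


def flag_death(
    track: CellTrack, params: SegmentationParams | None = None
) -> tuple[bool, int | None]:
    """Detect cell collapse: area *or* mean OPL persistently below a
    fraction of its initial-window median.

    Returns ``(flag, earliest_frame)`` and also records them on the track.
    Tracks shorter than 3 frames are never flagged (a warning is emitted).
    """
    params = params or SegmentationParams()
    if track.n_frames < 3:
        warnings.warn(
            f"track {track.track_id} too short ({track.n_frames} frames) "
            "for death detection",
            stacklevel=2,
        )
        track.death_flag, track.death_frame = False, None
        return False, None

    frames, areas = track.series("area_px")
    _, opls = track.series("mean_opl_nm")
    w = min(params.death_init_window, track.n_frames)
    area_ref = float(np.median(areas[:w]))
    opl_ref = float(np.median(opls[:w]))
    below = (areas < params.death_fraction * area_ref) | (
        opls < params.death_fraction * opl_ref
    )
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= params.death_min_run:
            first = int(frames[i - params.death_min_run + 1])
            track.death_flag, track.death_frame = True, first
            return True, first
    track.death_flag, track.death_frame = False, None
    return False, None
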