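"""Uptake kinetics from per-cell roughness-kurtosis time series.

Turns each cell's kurtosis series into a verdict and, for accepted cells,
one detected uptake event: robust baseline (median / scaled MAD), prominent
single-peak detection with interpolated baseline crossings, the curation
rules used on real recordings (reject cells that never peak, peak already at
t = 0, die before uptake, or have outlier roughness), onset alignment,
cohort mean +/- SEM, per-cell internalisation widths, and between-group
fold-change of the mean width.

Detection runs on kurtosis by default; the skewness channel can be selected
for negative-control comparisons but is never used for acceptance decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .roughness import RoughnessSeries
from .segmentation import CellTrack

__all__ = [
    "KineticsParams",
    "BaselineModel",
    "UptakeEventDetected",
    "CellVerdict",
    "CohortSummary",
    "GroupComparison",
    "InsufficientDataError",
    "EmptyCohortError",
    "estimate_baseline",
    "detect_event",
    "classify_cell",
    "align_cohort",
    "internalisation_stats",
    "compare_groups",
]

REJECTION_REASONS = ("no_peak", "t0_peak", "pre_uptake_death", "outlier_roughness")


class InsufficientDataError(ValueError):
    """Series has too few valid points for a baseline estimate."""


class EmptyCohortError(RuntimeError):
    """No accepted cells to align or summarise."""


@dataclass(frozen=True)
class KineticsParams:
    k_sigma: float = 5.0  # prominence threshold in robust-sigma units
    min_width_frames: int = 2  # minimum above-baseline run supporting a peak
    outlier_factor: float = 5.0  # x cohort-median baseline level
    channel: str = "rku"  # detection channel; "rsk" for the negative control
    width_method: str = "crossing"  # "crossing" (baseline+sigma) or "fwhm"
    crossing_estimate: str = "midpoint"  # "midpoint" or "linear" interpolation
    min_baseline_points: int = 5

    def __post_init__(self):
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_width_frames < 1:
            raise ValueError("min_width_frames must be >= 1")
        if self.channel not in ("rku", "rsk"):
            raise ValueError("channel must be 'rku' or 'rsk'")
        if self.width_method not in ("crossing", "fwhm"):
            raise ValueError("width_method must be 'crossing' or 'fwhm'")
        if self.crossing_estimate not in ("midpoint", "linear"):
            raise ValueError("crossing_estimate must be 'midpoint' or 'linear'")


@dataclass(frozen=True)
class BaselineModel:
    level: float
    sigma: float  # robust noise scale, 1.4826 * MAD

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class UptakeEventDetected:
    track_id: int
    onset_time_min: float
    peak_time_min: float
    end_time_min: float
    width_min: float
    prominence: float
    multiple_candidates: bool = False  # other prominent peaks were discarded

    def __post_init__(self):
        if not (self.onset_time_min <= self.peak_time_min <= self.end_time_min):
            raise ValueError("require onset <= peak <= end")
        if self.width_min <= 0:
            raise ValueError("width must be positive")
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")


@dataclass(frozen=True)
class CellVerdict:
    track_id: int
    status: str  # "accepted" | "rejected"
    reason: str | None = None
    event: UptakeEventDetected | None = None

    def __post_init__(self):
        if self.status not in ("accepted", "rejected"):
            raise ValueError("status must be 'accepted' or 'rejected'")
        if self.status == "rejected" and self.reason not in REJECTION_REASONS:
            raise ValueError(f"rejection reason must be one of {REJECTION_REASONS}")
        if self.status == "accepted" and self.event is None:
            raise ValueError("accepted cells carry exactly one detected event")


@dataclass
class CohortSummary:
    """Onset-aligned kurtosis matrix with mean +/- SEM profile."""

    group: str
    aligned_times_min: np.ndarray
    rows: np.ndarray  # (n_cells, n_points), NaN outside each cell's support
    mean: np.ndarray
    sem: np.ndarray  # NaN where fewer than 2 cells contribute
    n_contributing: np.ndarray
    track_ids: list[int]
    onsets_min: np.ndarray  # original (pre-alignment) onset times
    widths_min: np.ndarray

    @property
    def n(self) -> int:
        return len(self.track_ids)

    @property
    def mean_width_min(self) -> float:
        return float(np.mean(self.widths_min))

    @property
    def mean_onset_min(self) -> float:
        return float(np.mean(self.onsets_min))


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_width_a_min: float
    mean_width_b_min: float
    fold_exact: float  # max/min, >= 1
    fold_rounded: float  # one decimal, as reported
    direction: str  # "decrease" | "increase" | "equal" (b relative to a)


# ---------------------------------------------------------------------------
# baseline and detection


def estimate_baseline(
    series: RoughnessSeries, params: KineticsParams | None = None
) -> BaselineModel:
    """Median level and scaled-MAD noise of the valid points.

    Both statistics are robust to a single transient event occupying up to
    ~40% of the series.
    """
    params = params or KineticsParams()
    vals = series.channel(params.channel)[series.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size < params.min_baseline_points:
        raise InsufficientDataError(
            f"baseline needs >= {params.min_baseline_points} valid points, "
            f"got {vals.size}"
        )
    level = float(np.median(vals))
    sigma = 1.4826 * float(np.median(np.abs(vals - level)))
    return BaselineModel(level=level, sigma=sigma)


def _interp_crossing(t0, v0, t1, v1, thresh, estimate="midpoint"):
    """Estimate where the series crossed ``thresh`` between two frames.

    ``"linear"`` interpolates the segment (exact for resolved, slowly
    varying signals but biased toward the sub-threshold frame when the
    rise saturates within one frame); ``"midpoint"`` takes the centre of
    the bracketing interval (at most half a frame off for any signal, and
    unbiased for steep peaks).
    """
    if estimate == "midpoint":
        return 0.5 * (t0 + t1)
    if v1 == v0:
        return t0
    return t0 + (thresh - v0) / (v1 - v0) * (t1 - t0)


def detect_event(
    series: RoughnessSeries,
    baseline: BaselineModel,
    params: KineticsParams | None = None,
) -> list[UptakeEventDetected]:
    """Detect the cell's uptake peak, if any.

    Candidate peaks are local maxima standing at least ``k_sigma * sigma``
    above the baseline level whose contiguous run above ``level + sigma``
    spans at least ``min_width_frames`` frames; candidates sharing one run
    are a single peak.  Onset is the (interpolated) last upward crossing of
    ``level + sigma`` before the peak, end the first return below it after
    the peak.  When several distinct candidates survive, only the most
    prominent is returned, flagged ``multiple_candidates``.
    """
    params = params or KineticsParams()
    if baseline.sigma == 0.0:
        return []
    times = series.times_min
    raw = series.channel(params.channel)
    v = np.where(series.valid & np.isfinite(raw), raw, baseline.level)

    run_level = baseline.level + baseline.sigma
    prom_min = params.k_sigma * baseline.sigma
    # pad with the baseline level so maxima at either boundary are detectable
    padded = np.concatenate(([baseline.level], v, [baseline.level]))
    idx, _ = find_peaks(padded)
    idx = idx - 1  # back to series coordinates

    above = v > run_level
    by_run: dict[tuple[int, int], tuple[float, int]] = {}
    for i in idx:
        prom = float(v[i] - baseline.level)  # excess over baseline
        if prom < prom_min or not above[i]:
            continue
        start = i
        while start > 0 and above[start - 1]:
            start -= 1
        stop = i
        while stop < len(v) - 1 and above[stop + 1]:
            stop += 1
        if stop - start + 1 < params.min_width_frames:
            continue
        key = (start, stop)
        if key not in by_run or prom > by_run[key][0]:
            by_run[key] = (prom, i)

    if not by_run:
        return []
    candidates = sorted(
        ((prom, i, start, stop) for (start, stop), (prom, i) in by_run.items()),
        key=lambda c: (-c[0], c[1]),
    )
    prom, i, start, stop = candidates[0]

    if params.width_method == "fwhm":
        half = baseline.level + 0.5 * (v[i] - baseline.level)
        lo = i
        while lo > 0 and v[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < len(v) - 1 and v[hi + 1] >= half:
            hi += 1
    else:
        half = run_level
        lo, hi = start, stop

    est = params.crossing_estimate
    if lo == 0:
        onset = float(times[0])
    else:
        onset = float(
            _interp_crossing(times[lo - 1], v[lo - 1], times[lo], v[lo], half, est)
        )
    if hi == len(v) - 1:
        end = float(times[-1])
    else:
        end = float(
            _interp_crossing(times[hi], v[hi], times[hi + 1], v[hi + 1], half, est)
        )

    onset = min(onset, float(times[i]))
    end = max(end, float(times[i]))
    width = end - onset
    if width <= 0:
        return []
    return [
        UptakeEventDetected(
            track_id=series.track_id,
            onset_time_min=onset,
            peak_time_min=float(times[i]),
            end_time_min=end,
            width_min=width,
            prominence=prom,
            multiple_candidates=len(candidates) > 1,
        )
    ]


# ---------------------------------------------------------------------------
# verdicts


def classify_cell(
    series: RoughnessSeries,
    events: list[UptakeEventDetected],
    track: CellTrack,
    baseline: BaselineModel,
    cohort_median_level: float,
    cohort_median_max: float | None = None,
    params: KineticsParams | None = None,
) -> CellVerdict:
    """Apply the curation rules with fixed precedence.

    pre_uptake_death > t0_peak > outlier_roughness > no_peak; anything left
    is accepted with its single surviving event.  The outlier rule compares
    a cell's baseline level (and series maximum) against the cohort medians
    of the same quantities.
    """
    params = params or KineticsParams()
    tid = series.track_id
    t0 = float(series.times_min[0])
    first_onset = min((ev.onset_time_min for ev in events), default=None)

    if track.death_flag:
        death_time = float(series.times_min[track.death_frame])
        if first_onset is None or death_time <= first_onset:
            return CellVerdict(tid, "rejected", reason="pre_uptake_death")

    if any(ev.onset_time_min <= t0 for ev in events):
        return CellVerdict(tid, "rejected", reason="t0_peak")

    # outlier screen: unusually high roughness *outside* any detected event
    # window (the uptake peak itself is not evidence of an abnormal cell)
    raw = series.channel(params.channel)
    keep = series.valid & np.isfinite(raw)
    for ev in events:
        keep &= ~(
            (series.times_min >= ev.onset_time_min)
            & (series.times_min <= ev.end_time_min)
        )
    finite = raw[keep]
    series_max = float(np.max(finite)) if finite.size else 0.0
    is_outlier = (
        cohort_median_level > 0
        and baseline.level > params.outlier_factor * cohort_median_level
    )
    if cohort_median_max is not None and cohort_median_max > 0:
        is_outlier = is_outlier or (
            series_max > params.outlier_factor * cohort_median_max
        )
    if is_outlier:
        return CellVerdict(tid, "rejected", reason="outlier_roughness")

    if not events:
        return CellVerdict(tid, "rejected", reason="no_peak")
    return CellVerdict(tid, "accepted", event=events[0])


# ---------------------------------------------------------------------------
# cohort aggregation


def align_cohort(
    accepted: list[tuple[RoughnessSeries, UptakeEventDetected]],
    group: str = "group",
    channel: str = "rku",
) -> CohortSummary:
    """Shift each accepted series so its onset maps to aligned time 0 and
    average across cells.

    Series are shifted by whole frames (nearest frame to the interpolated
    onset), the union of shifted supports defines the aligned axis, and at
    each aligned point the mean and SEM (sd/sqrt(n), n >= 2) are taken over
    contributing cells.
    """
    if not accepted:
        raise EmptyCohortError("no accepted cells to align")
    dt = float(np.diff(accepted[0][0].times_min)[0]) if len(accepted[0][0].times_min) > 1 else 1.0

    shifts = []
    for series, event in accepted:
        k = int(round((event.onset_time_min - series.times_min[0]) / dt))
        shifts.append(k)
    n_frames = len(accepted[0][0].times_min)
    lo = -max(shifts)
    hi = n_frames - 1 - min(shifts)
    n_points = hi - lo + 1
    aligned_times = (np.arange(lo, hi + 1)) * dt

    rows = np.full((len(accepted), n_points), np.nan)
    for row, ((series, event), k) in enumerate(zip(accepted, shifts)):
        vals = np.where(series.valid, series.channel(channel), np.nan)
        start = -k - lo
        rows[row, start : start + n_frames] = vals

    n_contrib = np.sum(np.isfinite(rows), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_contrib > 0, np.nanmean(np.where(np.isfinite(rows), rows, np.nan), axis=0), np.nan)
    sem = np.full(n_points, np.nan)
    for j in range(n_points):
        col = rows[:, j]
        col = col[np.isfinite(col)]
        if col.size >= 2:
            sem[j] = np.std(col, ddof=1) / math.sqrt(col.size)

    return CohortSummary(
        group=group,
        aligned_times_min=aligned_times,
        rows=rows,
        mean=mean,
        sem=sem,
        n_contributing=n_contrib,
        track_ids=[s.track_id for s, _ in accepted],
        onsets_min=np.array([e.onset_time_min for _, e in accepted]),
        widths_min=np.array([e.width_min for _, e in accepted]),
    )


def internalisation_stats(
    cohort: CohortSummary,
) -> tuple[float, float, np.ndarray]:
    """(mean onset, mean width, per-cell widths) in minutes.

    Report-facing values are rounded to one decimal elsewhere; full
    precision is returned here.
    """
    if cohort.n < 1:
        raise EmptyCohortError("cohort has no cells")
    return cohort.mean_onset_min, cohort.mean_width_min, cohort.widths_min.copy()


def compare_groups(a: CohortSummary, b: CohortSummary) -> GroupComparison:
    """Fold change of mean internalisation widths between two cohorts.

    The fold is larger-over-smaller (>= 1), reported at one decimal with the
    direction of group b relative to group a.
    """
    wa, wb = a.mean_width_min, b.mean_width_min
    if wa <= 0 or wb <= 0:
        raise ValueError("fold change undefined for non-positive mean widths")
    fold = max(wa, wb) / min(wa, wb)
    if wb < wa:
        direction = "decrease"
    elif wb > wa:
        direction = "increase"
    else:
        direction = "equal"
    return GroupComparison(
        group_a=a.group,
        group_b=b.group,
        mean_width_a_min=wa,
        mean_width_b_min=wb,
        fold_exact=fold,
        fold_rounded=round(fold, 1),
        direction=direction,
    )
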