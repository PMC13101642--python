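"""Per-cell surface-roughness descriptors on detrended intra-cell heights.

For every tracked cell at every frame, the intra-cell optical-path-length
values are detrended by a least-squares polynomial surface (order 2 by
default, removing the gross dome shape) and the residual "texture" is
summarised by surface-metrology moment descriptors:

    Rq  = sqrt(mean(z^2))        RMS roughness (nm)
    Rsk = mean(z^3) / Rq^3       roughness skewness (dimensionless)
    Rku = mean(z^4) / Rq^4       roughness kurtosis (dimensionless)

Population (biased) moments are used throughout, so a Gaussian texture has
Rku -> 3 and Rsk -> 0, and the Pearson bound Rku >= Rsk^2 + 1 always holds.
Because Rsk and Rku are scale-invariant, computing on OPL rather than phase
changes nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import FrameStack
from .segmentation import CellTrack

__all__ = [
    "RoughnessParams",
    "RoughnessSample",
    "RoughnessSeries",
    "detrend",
    "descriptors",
    "compute_series",
]

#: minimum pixels for a solvable order-2 surface fit
MIN_REGION_PIXELS = 6


@dataclass(frozen=True)
class RoughnessParams:
    detrend_order: int = 2  # 0 (mean), 1 (plane) or 2 (quadratic surface)
    min_pixels: int = MIN_REGION_PIXELS

    def __post_init__(self):
        if self.detrend_order not in (0, 1, 2):
            raise ValueError("detrend_order must be 0, 1 or 2")
        if self.min_pixels < MIN_REGION_PIXELS:
            raise ValueError(f"min_pixels must be >= {MIN_REGION_PIXELS}")


@dataclass(frozen=True)
class RoughnessSample:
    track_id: int
    frame: int
    time_min: float
    n_px: int
    mean_height_nm: float
    rq_nm: float
    rsk: float  # NaN when undefined (Rq == 0 or region too small)
    rku: float
    valid: bool


@dataclass
class RoughnessSeries:
    """One cell's roughness descriptors over time (NaN where invalid)."""

    track_id: int
    times_min: np.ndarray
    rq: np.ndarray
    rsk: np.ndarray
    rku: np.ndarray
    n_px: np.ndarray
    valid: np.ndarray  # bool: cell present and region large enough

    def __post_init__(self):
        n = len(self.times_min)
        for name in ("rq", "rsk", "rku", "n_px", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match times")

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def channel(self, name: str) -> np.ndarray:
        if name not in ("rku", "rsk", "rq"):
            raise ValueError(f"unknown roughness channel {name!r}")
        return getattr(self, name)


def _design_matrix(rows: np.ndarray, cols: np.ndarray, order: int) -> np.ndarray:
    # centred/scaled coordinates keep the normal equations well conditioned
    r = rows - rows.mean()
    c = cols - cols.mean()
    scale = max(np.ptp(r), np.ptp(c), 1.0)
    r = r / scale
    c = c / scale
    terms = [np.ones_like(r)]
    if order >= 1:
        terms += [r, c]
    if order >= 2:
        terms += [r * c, r**2, c**2]
    return np.column_stack(terms)


def detrend(
    rows: np.ndarray, cols: np.ndarray, heights: np.ndarray, order: int = 2
) -> np.ndarray:
    """Remove a least-squares polynomial surface; residuals are zero-mean.

    Raises ``ValueError`` when the region has fewer pixels than the fit
    needs (callers treat that as an invalid sample rather than an error).
    """
    heights = np.asarray(heights, dtype=float)
    n_coef = {0: 1, 1: 3, 2: 6}[order]
    if heights.size < max(n_coef, MIN_REGION_PIXELS):
        raise ValueError(
            f"region of {heights.size} px too small for order-{order} detrend"
        )
    X = _design_matrix(np.asarray(rows, float), np.asarray(cols, float), order)
    coef, *_ = np.linalg.lstsq(X, heights, rcond=None)
    resid = heights - X @ coef
    return resid - resid.mean()  # exact zero mean regardless of conditioning


def descriptors(residuals: np.ndarray) -> tuple[float, float, float]:
    """(Rq, Rsk, Rku) from zero-mean residuals; NaN skew/kurtosis when Rq=0."""
    z = np.asarray(residuals, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 residuals")
    scale = float(np.max(np.abs(z)))
    if scale == 0.0:
        return 0.0, float("nan"), float("nan")
    zs = z / scale  # pre-scaling avoids under/overflow in the powers
    m2 = float(np.mean(zs**2))
    rq = float(np.sqrt(m2))
    if rq == 0.0:
        return 0.0, float("nan"), float("nan")
    u = zs / rq
    rsk = float(np.mean(u**3))
    rku = float(np.mean(u**4))
    return rq * scale, rsk, rku


def compute_series(
    stack: FrameStack,
    tracks: list[CellTrack],
    params: RoughnessParams | None = None,
) -> list[RoughnessSeries]:
    """Extract-detrend-describe every tracked region in every frame.

    Returns one :class:`RoughnessSeries` per track, ordered by ``track_id``,
    on the full stack time axis with invalid frames masked (cell absent or
    region below ``min_pixels``).
    """
    params = params or RoughnessParams()
    times = stack.timestamps_min
    n = stack.n_frames
    out: list[RoughnessSeries] = []
    for track in sorted(tracks, key=lambda tr: tr.track_id):
        rq = np.full(n, np.nan)
        rsk = np.full(n, np.nan)
        rku = np.full(n, np.nan)
        npx = np.zeros(n, dtype=int)
        valid = np.zeros(n, dtype=bool)
        for frame_idx, obs in track.observations.items():
            if frame_idx >= n:
                raise ValueError(
                    f"track {track.track_id} references frame {frame_idx} "
                    f"outside stack of {n} frames"
                )
            rows, cols = obs.pixels
            npx[frame_idx] = rows.size
            if rows.size < params.min_pixels:
                continue
            heights = stack.data[frame_idx][rows, cols].astype(float)
            resid = detrend(rows, cols, heights, order=params.detrend_order)
            q, s, k = descriptors(resid)
            rq[frame_idx] = q
            rsk[frame_idx] = s
            rku[frame_idx] = k
            valid[frame_idx] = np.isfinite(k)
        out.append(
            RoughnessSeries(
                track_id=track.track_id,
                times_min=times.copy(),
                rq=rq,
                rsk=rsk,
                rku=rku,
                n_px=npx,
                valid=valid,
            )
        )
    return out
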