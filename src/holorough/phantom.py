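"""Synthetic quantitative-phase time-lapse generator.

Emulates the statistical structure of digital holographic microscopy (DHM)
recordings of adherent cells during nanoparticle (NP) uptake: each cell is a
smooth optical-path-length (OPL) dome carrying spatially correlated,
temporally autocorrelated membrane-fluctuation texture; an uptake event adds
a transient cluster of localized OPL perturbations (particle bumps and
endocytic pits) whose time course follows an asymmetric raised-cosine
envelope.  Frames are stored as OPL in nanometres; conversion to optical
phase goes through :func:`phase_shift`.

Every cell has a *fate* mirroring the exclusion taxonomy used when curating
real recordings:

``normal``
    live cell; may carry one uptake event.
``quiescent``
    live cell, no NP interaction (control behaviour).
``t0_peak``
    uptake already in progress at the first frame (rejected downstream).
``dying``
    cell whose dome collapses at ``death_frame`` (rejected when death
    precedes uptake).
``fixed``
    chemically fixed cell: membrane fluctuations damped by a factor < 1.

The generator is fully deterministic given a seed; each cell consumes its
own child random stream keyed by ``cell_id``, so adding a cell never changes
the noise of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FATES",
    "OpticalConfig",
    "SceneConfig",
    "CellPhantom",
    "UptakeEventSpec",
    "GroundTruth",
    "FrameStack",
    "PlacementError",
    "phase_shift",
    "thickness_from_phase",
    "event_envelope",
    "sample_phantoms",
    "render_frame",
    "simulate",
]

FATES = ("normal", "quiescent", "t0_peak", "dying", "fixed")

# sub-stream tags: keep per-purpose RNG lineages independent of one another
_STREAM_SCENE = 11
_STREAM_CELL_NOISE = 23
_STREAM_CELL_PARAMS = 37
_STREAM_BACKGROUND = 51
_STREAM_CELL_STATIC = 67


class PlacementError(RuntimeError):
    """Field too small to place the requested number of non-overlapping cells."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} cells without overlap"
        )


# ---------------------------------------------------------------------------
# optics


def phase_shift(wavelength_nm: float, refractive_index: float, thickness_nm) -> float:
    """Phase delay (radians) of light crossing a slab: (2*pi/lambda) * n * x.

    ``thickness_nm`` may be a scalar or array.  With ``n`` interpreted as the
    effective index contrast against the medium, ``n * x`` is the optical
    path length that DHM reconstructs.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    thickness_nm = np.asarray(thickness_nm, dtype=float)
    if np.any(thickness_nm < 0):
        raise ValueError("thickness must be non-negative")
    out = (2.0 * np.pi / wavelength_nm) * refractive_index * thickness_nm
    return float(out) if out.ndim == 0 else out


def thickness_from_phase(wavelength_nm: float, refractive_index: float, phase_rad):
    """Inverse of :func:`phase_shift`: thickness (nm) from phase (radians)."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if refractive_index == 0:
        raise ValueError("refractive index must be non-zero")
    phase_rad = np.asarray(phase_rad, dtype=float)
    out = phase_rad * wavelength_nm / (2.0 * np.pi * refractive_index)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and cadence of the emulated instrument.

    Defaults follow a HoloMonitor-class time-lapse run: one frame per minute
    for an hour over a ~1.25 mm x 1.25 mm field.
    """

    wavelength_nm: float = 635.0
    refractive_index: float = 1.37
    pixel_pitch_um: float = 1.22
    field_size: tuple[int, int] = (1024, 1024)
    frame_interval_min: float = 1.0
    duration_min: float = 60.0

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        if self.duration_min < 0:
            raise ValueError("duration must be non-negative")
        if len(self.field_size) != 2 or min(self.field_size) < 1:
            raise ValueError("field_size must be (rows, cols) with positive sizes")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_min / self.frame_interval_min)) + 1

    @property
    def timestamps_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size"] = list(self.field_size)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "OpticalConfig":
        d = dict(d)
        d["field_size"] = tuple(d.get("field_size", (1024, 1024)))
        return cls(**d)


@dataclass(frozen=True)
class SceneConfig:
    """Population-level description of a simulated field of cells.

    The default scene mirrors a single uptake experiment: about forty cells
    in the field, of which five interact with NPs (one discrete uptake event
    each), one is already peaking at t = 0, three die during the recording,
    and the remainder show only baseline membrane dynamics.
    """

    n_cells: int = 40
    fate_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "normal": 0.125,
            "quiescent": 0.775,
            "t0_peak": 0.025,
            "dying": 0.075,
        }
    )

    # cell geometry / optics (pixels, nm of OPL)
    semi_axis_range_px: tuple[float, float] = (13.0, 18.0)
    peak_thickness_range_nm: tuple[float, float] = (300.0, 500.0)

    # membrane dynamics and frozen internal structure
    fluctuation_amplitude_nm: float = 4.0
    fluctuation_corr_length_px: float = 1.0
    fluctuation_timescale_frames: float = 3.0
    static_texture_amplitude_nm: float = 6.0
    fixed_damping: float = 0.3

    # uptake events
    event_onset_mean_min: float = 15.0
    event_onset_sd_min: float = 3.0
    event_onset_range_min: tuple[float, float] = (5.0, 40.0)
    event_duration_mean_min: float = 7.2
    event_duration_sd_min: float = 1.5
    event_duration_range_min: tuple[float, float] = (2.0, 9.0)
    event_amplitude_nm: float = 230.0
    event_n_sites: int = 4
    event_site_sigma_px: float = 1.2
    event_rise_fraction: float = 0.55
    single_event_per_cell: bool = True

    # cell death
    death_time_range_min: tuple[float, float] = (5.0, 40.0)
    death_tau_min: float = 2.0

    # field-level nuisance
    background_sigma_nm: float = 1.5
    placement_margin_px: float = 4.0
    max_place_tries: int = 200

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        mix = dict(self.fate_mix)
        unknown = set(mix) - set(FATES)
        if unknown:
            raise ValueError(f"unknown fates in mixture: {sorted(unknown)}")
        if mix and not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("fate mixture proportions must sum to 1")
        if not 0 <= self.fixed_damping < 1:
            raise ValueError("fixed_damping must lie in [0, 1)")
        if not 0 <= self.event_rise_fraction < 1:
            raise ValueError("event_rise_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fate_mix"] = dict(self.fate_mix)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        d = dict(d)
        for k in (
            "semi_axis_range_px",
            "peak_thickness_range_nm",
            "event_onset_range_min",
            "event_duration_range_min",
            "death_time_range_min",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# ground-truth records


@dataclass(frozen=True)
class CellPhantom:
    cell_id: int
    centroid_rc: tuple[float, float]
    semi_axes_px: tuple[float, float]
    peak_thickness_nm: float
    fluctuation_amplitude_nm: float
    fluctuation_corr_length_px: float
    fluctuation_timescale_frames: float
    fate: str
    death_time_min: float | None = None
    static_texture_amplitude_nm: float = 0.0

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if min(self.semi_axes_px) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.peak_thickness_nm <= 0:
            raise ValueError("peak thickness must be positive")
        if self.fluctuation_amplitude_nm < 0:
            raise ValueError("fluctuation amplitude must be non-negative")
        if self.fate == "dying" and self.death_time_min is None:
            raise ValueError("dying fate requires death_time_min")

    @property
    def bounding_radius_px(self) -> float:
        return float(max(self.semi_axes_px))

    def footprint_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the cell's elliptical footprint on a full frame."""
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        a, b = self.semi_axes_px
        r0, c0 = self.centroid_rc
        return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0

    def footprint_area_px(self) -> float:
        return math.pi * self.semi_axes_px[0] * self.semi_axes_px[1]


@dataclass(frozen=True)
class UptakeEventSpec:
    """One NP adsorption -> internalisation event on one cell.

    ``site_offsets_px`` are (row, col) offsets of the perturbation spots from
    the cell centroid; ``site_weights`` are signed relative heights.  Signs
    alternate between particle bumps (+) and endocytic pits (-) and the
    weights are balanced so the cubes sum to zero, making the perturbation
    skewness-neutral while still heavy-tailed: the event registers in
    kurtosis but not in skewness, matching the observed channel asymmetry.
    """

    cell_id: int
    onset_min: float
    duration_min: float
    amplitude_nm: float
    n_sites: int
    site_sigma_px: float
    rise_fraction: float = 0.55
    site_offsets_px: tuple[tuple[float, float], ...] = ()
    site_weights: tuple[float, ...] = ()

    def __post_init__(self):
        if self.onset_min < 0:
            raise ValueError("onset must be non-negative")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude_nm < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.rise_fraction < 1:
            raise ValueError("rise_fraction must lie in [0, 1)")

    @property
    def peak_time_min(self) -> float:
        return self.onset_min + self.rise_fraction * self.duration_min

    @property
    def end_min(self) -> float:
        return self.onset_min + self.duration_min


def balanced_site_weights(n_sites: int) -> tuple[float, ...]:
    """Signed spot heights with sum of cubes == 0 (for n >= 2).

    Odd sites get +1; even sites share a common negative weight chosen so
    that the third moments of bumps and pits cancel exactly.  This is the
    analytic balance for non-overlapping identical profiles; the generator
    refines it per event against the cell's detrending basis with
    :func:`neutral_site_weights`.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if n_sites == 1:
        return (1.0,)
    n_pos = (n_sites + 1) // 2
    n_neg = n_sites - n_pos
    w_neg = -((n_pos / n_neg) ** (1.0 / 3.0))
    return tuple(1.0 if i % 2 == 0 else w_neg for i in range(n_sites))


def _quadratic_residual(rows, cols, vals):
    # order-2 surface removal, mirroring the analysis-side detrend
    r = rows - rows.mean()
    c = cols - cols.mean()
    s = max(np.ptp(r), np.ptp(c), 1.0)
    r = r / s
    c = c / s
    X = np.column_stack([np.ones_like(r), r, c, r * c, r * r, c * c])
    coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
    res = vals - X @ coef
    return res - res.mean()


def neutral_site_weights(
    cell: CellPhantom, offsets: Sequence[tuple[float, float]], site_sigma_px: float
) -> tuple[float, ...]:
    """Site weights making the *detrended* spot pattern skewness-free.

    Bumps (odd sites, +1) and pits (even sites, scaled by a common factor
    -beta) interact with the quadratic detrending surface, so the analytic
    cube balance of :func:`balanced_site_weights` is only approximate.
    Here beta is solved exactly: with P and Q the detrend residuals of the
    bump and pit fields on the cell footprint, sum((P - beta*Q)^3) = 0 is a
    cubic in beta whose real positive root nearest the analytic balance is
    taken.  The event then perturbs tail weight (kurtosis) without biasing
    asymmetry (skewness) — the channel asymmetry the recordings show.
    """
    n = len(offsets)
    default = balanced_site_weights(n)
    if n < 2:
        return default
    r0, c0 = cell.centroid_rc
    a, b = cell.semi_axes_px
    rr = np.arange(int(math.floor(r0 - a)), int(math.ceil(r0 + a)) + 1)[:, None]
    cc = np.arange(int(math.floor(c0 - b)), int(math.ceil(c0 + b)) + 1)[None, :]
    inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    rows, cols = np.nonzero(inside)
    rows = rows + int(math.floor(r0 - a))
    cols = cols + int(math.floor(c0 - b))
    s2 = 2.0 * site_sigma_px**2
    P = np.zeros(rows.size)
    Q = np.zeros(rows.size)
    for i, (dr, dc) in enumerate(offsets):
        g = np.exp(-((rows - (r0 + dr)) ** 2 + (cols - (c0 + dc)) ** 2) / s2)
        if i % 2 == 0:
            P += g
        else:
            Q += g
    P = _quadratic_residual(rows.astype(float), cols.astype(float), P)
    Q = _quadratic_residual(rows.astype(float), cols.astype(float), Q)
    # sum((P - beta Q)^3) = a0 - 3 a1 b + 3 a2 b^2 - a3 b^3
    a0 = float(np.sum(P**3))
    a1 = float(np.sum(P**2 * Q))
    a2 = float(np.sum(P * Q**2))
    a3 = float(np.sum(Q**3))
    roots = np.roots([-a3, 3 * a2, -3 * a1, a0]) if a3 != 0 else np.roots(
        [3 * a2, -3 * a1, a0]
    )
    beta0 = -min(default)
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and r.real > 0]
    beta = min(real, key=lambda x: abs(x - beta0)) if real else beta0
    return tuple(1.0 if i % 2 == 0 else -beta for i in range(n))


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellPhantom, ...]
    events: tuple[UptakeEventSpec, ...]
    seed: int
    optical: OpticalConfig
    scene: SceneConfig

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")
        known = set(ids)
        for ev in self.events:
            if ev.cell_id not in known:
                raise ValueError(f"event references unknown cell {ev.cell_id}")

    def events_for(self, cell_id: int) -> tuple[UptakeEventSpec, ...]:
        return tuple(ev for ev in self.events if ev.cell_id == cell_id)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "seed": self.seed,
            "optical": self.optical.to_dict(),
            "scene": self.scene.to_dict(),
            "cells": [
                {**asdict(c), "centroid_rc": list(c.centroid_rc),
                 "semi_axes_px": list(c.semi_axes_px)}
                for c in self.cells
            ],
            "events": [
                {**asdict(e),
                 "site_offsets_px": [list(s) for s in e.site_offsets_px],
                 "site_weights": list(e.site_weights)}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported schema version {d.get('schema_version')!r}")
        cells = tuple(
            CellPhantom(**{**c, "centroid_rc": tuple(c["centroid_rc"]),
                           "semi_axes_px": tuple(c["semi_axes_px"])})
            for c in d["cells"]
        )
        events = tuple(
            UptakeEventSpec(
                **{**e,
                   "site_offsets_px": tuple(tuple(s) for s in e["site_offsets_px"]),
                   "site_weights": tuple(e["site_weights"])}
            )
            for e in d["events"]
        )
        return cls(
            cells=cells,
            events=events,
            seed=int(d["seed"]),
            optical=OpticalConfig.from_dict(d["optical"]),
            scene=SceneConfig.from_dict(d["scene"]),
        )


@dataclass
class FrameStack:
    """Time-ordered OPL maps (nm): the raw input of the analysis pipeline."""

    data: np.ndarray  # (T, H, W) float32, non-negative
    pixel_pitch_um: float
    frame_interval_min: float
    timestamps_min: np.ndarray
    wavelength_nm: float = 635.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (T, H, W)")
        if len(self.timestamps_min) != self.data.shape[0]:
            raise ValueError("one timestamp per frame required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame data must be finite")
        dt = np.diff(self.timestamps_min)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must increase with constant spacing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


# ---------------------------------------------------------------------------
# envelope


def event_envelope(t, event: UptakeEventSpec):
    """Scale factor in [0, 1] for an event at time(s) ``t`` (minutes).

    Asymmetric raised cosine: rises over ``rise_fraction * duration`` to a
    single maximum of 1, then falls over the remainder; identically 0 outside
    ``[onset, onset + duration]``.  ``rise_fraction == 0`` degenerates to a
    pure decay with its maximum at onset (used for uptake already in
    progress at the first frame).
    """
    t = np.asarray(t, dtype=float)
    u = (t - event.onset_min) / event.duration_min
    rho = event.rise_fraction
    out = np.zeros_like(u)
    if rho > 0:
        rising = (u >= 0) & (u < rho)
        out[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / rho))
    falling = (u >= rho) & (u < 1.0)
    out[falling] = 0.5 * (1.0 + np.cos(np.pi * (u[falling] - rho) / (1.0 - rho)))
    # close the envelope exactly at the end of the event
    out[u >= 1.0] = 0.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# scene sampling


def _fate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of fates."""
    fates = [f for f in FATES if mix.get(f, 0.0) > 0]
    raw = {f: n * mix[f] for f in fates}
    counts = {f: int(math.floor(raw[f])) for f in fates}
    short = n - sum(counts.values())
    by_rem = sorted(fates, key=lambda f: (raw[f] - counts[f], f), reverse=True)
    for f in by_rem[:short]:
        counts[f] += 1
    return counts


def _sample_event(
    cell: CellPhantom, scene: SceneConfig, rng: np.random.Generator
) -> UptakeEventSpec:
    if cell.fate == "t0_peak":
        onset = 0.0
        rise = 0.0
    else:
        onset = float(
            np.clip(
                rng.normal(scene.event_onset_mean_min, scene.event_onset_sd_min),
                *scene.event_onset_range_min,
            )
        )
        rise = scene.event_rise_fraction
    duration = float(
        np.clip(
            rng.normal(scene.event_duration_mean_min, scene.event_duration_sd_min),
            *scene.event_duration_range_min,
        )
    )
    # sites in the inner 0.4-ellipse of the footprint, where the dome is
    # tall enough that pits never undercut it into negative OPL
    a, b = cell.semi_axes_px
    offsets = []
    for _ in range(scene.event_n_sites):
        while True:
            dr = rng.uniform(-0.4 * a, 0.4 * a)
            dc = rng.uniform(-0.4 * b, 0.4 * b)
            if (dr / a) ** 2 + (dc / b) ** 2 <= 0.16:
                offsets.append((float(dr), float(dc)))
                break
    return UptakeEventSpec(
        cell_id=cell.cell_id,
        onset_min=onset,
        duration_min=duration,
        amplitude_nm=scene.event_amplitude_nm,
        n_sites=scene.event_n_sites,
        site_sigma_px=scene.event_site_sigma_px,
        rise_fraction=rise,
        site_offsets_px=tuple(offsets),
        site_weights=neutral_site_weights(
            cell, offsets, scene.event_site_sigma_px
        ),
    )


def sample_phantoms(
    optical: OpticalConfig, scene: SceneConfig, seed: int
) -> GroundTruth:
    """Place non-overlapping cell phantoms and assign fates and events.

    Placement is rejection sampling of bounding circles with a configured
    margin; if ``max_place_tries`` successive rejections occur for one cell a
    :class:`PlacementError` reporting the achieved count is raised.
    """
    h, w = optical.field_size
    counts = _fate_counts(scene.n_cells, scene.fate_mix) if scene.n_cells else {}
    fate_list: list[str] = []
    for f in FATES:
        fate_list.extend([f] * counts.get(f, 0))
    rng_scene = np.random.default_rng([seed, _STREAM_SCENE])
    fate_list = list(rng_scene.permutation(np.array(fate_list, dtype=object)))

    cells: list[CellPhantom] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, bounding radius)
    for cid in range(scene.n_cells):
        rng_cell = np.random.default_rng([seed, _STREAM_CELL_PARAMS, cid])
        a = rng_cell.uniform(*scene.semi_axis_range_px)
        b = rng_cell.uniform(*scene.semi_axis_range_px)
        peak = rng_cell.uniform(*scene.peak_thickness_range_nm)
        rad = max(a, b)
        ok = False
        for _ in range(scene.max_place_tries):
            r0 = rng_cell.uniform(rad + 1, h - rad - 1)
            c0 = rng_cell.uniform(rad + 1, w - rad - 1)
            if all(
                math.hypot(r0 - pr, c0 - pc)
                > rad + prad + scene.placement_margin_px
                for pr, pc, prad in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(scene.n_cells, len(cells))
        fate = str(fate_list[cid])
        death = (
            float(rng_cell.uniform(*scene.death_time_range_min))
            if fate == "dying"
            else None
        )
        cells.append(
            CellPhantom(
                cell_id=cid,
                centroid_rc=(float(r0), float(c0)),
                semi_axes_px=(float(a), float(b)),
                peak_thickness_nm=float(peak),
                fluctuation_amplitude_nm=scene.fluctuation_amplitude_nm,
                fluctuation_corr_length_px=scene.fluctuation_corr_length_px,
                fluctuation_timescale_frames=scene.fluctuation_timescale_frames,
                fate=fate,
                death_time_min=death,
                static_texture_amplitude_nm=scene.static_texture_amplitude_nm,
            )
        )
        placed.append((r0, c0, rad))

    events: list[UptakeEventSpec] = []
    for cell in cells:
        if cell.fate not in ("normal", "t0_peak"):
            continue
        rng_ev = np.random.default_rng([seed, _STREAM_CELL_PARAMS, cell.cell_id, 7])
        n_events = 1 if scene.single_event_per_cell else int(rng_ev.integers(1, 3))
        for _ in range(n_events):
            events.append(_sample_event(cell, scene, rng_ev))

    return GroundTruth(
        cells=tuple(cells),
        events=tuple(events),
        seed=int(seed),
        optical=optical,
        scene=scene,
    )


# ---------------------------------------------------------------------------
# rendering


def _cell_bbox(cell: CellPhantom, shape: tuple[int, int], pad: int = 3):
    r0, c0 = cell.centroid_rc
    a, b = cell.semi_axes_px
    rlo = max(0, int(math.floor(r0 - a)) - pad)
    rhi = min(shape[0], int(math.ceil(r0 + a)) + pad + 1)
    clo = max(0, int(math.floor(c0 - b)) - pad)
    chi = min(shape[1], int(math.ceil(c0 + b)) + pad + 1)
    return rlo, rhi, clo, chi


def _dome_and_mask(cell: CellPhantom, shape, bbox):
    rlo, rhi, clo, chi = bbox
    rr = np.arange(rlo, rhi)[:, None]
    cc = np.arange(clo, chi)[None, :]
    a, b = cell.semi_axes_px
    r0, c0 = cell.centroid_rc
    u2 = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2
    mask = u2 <= 1.0
    dome = np.zeros(u2.shape)
    # paraboloidal cap: an exact quadratic in (row, col), so the gross cell
    # shape is removed exactly by quadratic detrending and the roughness
    # descriptors see only texture
    dome[mask] = cell.peak_thickness_nm * (1.0 - u2[mask])
    return dome, mask


def _fluctuation_innovation(
    cell: CellPhantom, bbox, rng: np.random.Generator
) -> np.ndarray:
    """Fresh unit-RMS correlated field over the cell's bounding box."""
    rlo, rhi, clo, chi = bbox
    white = rng.standard_normal((rhi - rlo, chi - clo))
    f = gaussian_filter(white, cell.fluctuation_corr_length_px, mode="reflect")
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def _static_texture(cell: CellPhantom, bbox, seed: int) -> np.ndarray:
    """Frozen per-cell internal-structure field (organelles, cytoskeleton):
    spatially correlated, symmetric, constant over the recording.

    Deterministic in (seed, cell_id); independent of the membrane
    fluctuation stream.
    """
    rng = np.random.default_rng([seed, _STREAM_CELL_STATIC, cell.cell_id])
    return cell.static_texture_amplitude_nm * _fluctuation_innovation(cell, bbox, rng)


def _spot_pattern(event: UptakeEventSpec, cell: CellPhantom, bbox) -> np.ndarray:
    rlo, rhi, clo, chi = bbox
    rr = np.arange(rlo, rhi)[:, None]
    cc = np.arange(clo, chi)[None, :]
    r0, c0 = cell.centroid_rc
    pat = np.zeros((rhi - rlo, chi - clo))
    s2 = 2.0 * event.site_sigma_px**2
    for (dr, dc), wgt in zip(event.site_offsets_px, event.site_weights):
        d2 = (rr - (r0 + dr)) ** 2 + (cc - (c0 + dc)) ** 2
        pat += wgt * np.exp(-d2 / s2)
    return pat


def _event_height_scale(env) -> np.ndarray | float:
    """Spot height as a function of the envelope value.

    Excess kurtosis of a small spot on Gaussian texture grows with the
    fourth power of the relative spot height, so heights follow the fourth
    root of the envelope: the *kurtosis* excursion then tracks the envelope
    itself, which is the time profile the recordings show.
    """
    return np.asarray(env, dtype=float) ** 0.25


def render_frame(
    truth: GroundTruth,
    t_min: float,
    optical: OpticalConfig | None = None,
    rng: np.random.Generator | None = None,
    state: dict | None = None,
) -> np.ndarray:
    """Render one OPL map (nm) at time ``t_min``.

    Without ``rng`` the render contains no noise draws (domes, frozen
    internal texture, decay and event spots only).  With ``rng`` and
    a persistent ``state`` dict (as used by :func:`simulate`), per-cell
    membrane fields follow an AR(1) update between calls; with ``rng`` but no
    ``state``, fluctuation fields are drawn fresh.
    """
    optical = optical or truth.optical
    shape = optical.field_size
    scene = truth.scene
    frame = np.zeros(shape)

    for cell in truth.cells:
        bbox = _cell_bbox(cell, shape)
        rlo, rhi, clo, chi = bbox
        dome, mask = _dome_and_mask(cell, shape, bbox)

        decay = 1.0
        if cell.fate == "dying" and t_min >= cell.death_time_min:
            decay = math.exp(-(t_min - cell.death_time_min) / scene.death_tau_min)

        local = dome * decay
        if cell.static_texture_amplitude_nm > 0:
            if state is not None:
                static = state.setdefault("static", {})
                if cell.cell_id not in static:
                    static[cell.cell_id] = _static_texture(cell, bbox, truth.seed)
                tex = static[cell.cell_id]
            else:
                tex = _static_texture(cell, bbox, truth.seed)
            local = local + tex * decay * mask

        amp = cell.fluctuation_amplitude_nm
        if cell.fate == "fixed":
            amp *= scene.fixed_damping
        if amp > 0 and rng is not None:
            if state is not None:
                cell_rng = state["cell_rngs"].setdefault(
                    cell.cell_id,
                    np.random.default_rng([truth.seed, _STREAM_CELL_NOISE, cell.cell_id]),
                )
                innov = _fluctuation_innovation(cell, bbox, cell_rng)
                prev = state["fields"].get(cell.cell_id)
                rho = math.exp(-1.0 / cell.fluctuation_timescale_frames)
                fld = innov if prev is None else rho * prev + math.sqrt(1 - rho**2) * innov
                state["fields"][cell.cell_id] = fld
            else:
                fld = _fluctuation_innovation(cell, bbox, rng)
            local = local + amp * decay * fld * mask

        for ev in truth.events_for(cell.cell_id):
            env = event_envelope(t_min, ev)
            if env > 0:
                local = local + (
                    ev.amplitude_nm * _event_height_scale(env) * _spot_pattern(ev, cell, bbox)
                ) * mask

        frame[rlo:rhi, clo:chi] += local

    if rng is not None and scene.background_sigma_nm > 0:
        frame += rng.normal(0.0, scene.background_sigma_nm, size=shape)
    np.clip(frame, 0.0, None, out=frame)
    return frame


def simulate(
    optical: OpticalConfig, scene: SceneConfig, seed: int
) -> tuple[FrameStack, GroundTruth]:
    """Run a full deterministic time-lapse simulation.

    Returns the rendered :class:`FrameStack` (``floor(duration/interval)+1``
    frames) and the :class:`GroundTruth` that produced it.  Identical inputs
    give bit-identical outputs.
    """
    truth = sample_phantoms(optical, scene, seed)
    bg_rng = np.random.default_rng([seed, _STREAM_BACKGROUND])
    state: dict = {"fields": {}, "cell_rngs": {}}
    frames = np.empty((optical.n_frames, *optical.field_size), dtype=np.float32)
    for i, t in enumerate(optical.timestamps_min):
        frames[i] = render_frame(truth, float(t), optical, rng=bg_rng, state=state)
    stack = FrameStack(
        data=frames,
        pixel_pitch_um=optical.pixel_pitch_um,
        frame_interval_min=optical.frame_interval_min,
        timestamps_min=optical.timestamps_min,
        wavelength_nm=optical.wavelength_nm,
    )
    return stack, truth
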