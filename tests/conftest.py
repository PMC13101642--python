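import numpy as np
import pytest

from holorough.phantom import (
    CellPhantom,
    GroundTruth,
    OpticalConfig,
    SceneConfig,
    UptakeEventSpec,
    balanced_site_weights,
)
from holorough.roughness import RoughnessSeries


@pytest.fixture
def small_optical():
    """A small field at the standard cadence, cheap enough for unit tests."""
    return OpticalConfig(field_size=(256, 256))


@pytest.fixture
def quiescent_scene():
    return SceneConfig(n_cells=6, fate_mix={"quiescent": 1.0})


def make_cell(cell_id=0, centroid=(128.0, 128.0), semi_axes=(15.0, 15.0),
              peak=300.0, fluct=0.0, fate="quiescent", death_time=None):
    return CellPhantom(
        cell_id=cell_id,
        centroid_rc=centroid,
        semi_axes_px=semi_axes,
        peak_thickness_nm=peak,
        fluctuation_amplitude_nm=fluct,
        fluctuation_corr_length_px=1.5,
        fluctuation_timescale_frames=3.0,
        fate=fate,
        death_time_min=death_time,
    )


def make_event(cell_id=0, onset=15.0, duration=7.2, amplitude=140.0,
               n_sites=3, site_sigma=1.2, rise=0.55,
               offsets=((0.0, 0.0), (4.0, 3.0), (-4.0, -3.0))):
    return UptakeEventSpec(
        cell_id=cell_id,
        onset_min=onset,
        duration_min=duration,
        amplitude_nm=amplitude,
        n_sites=n_sites,
        site_sigma_px=site_sigma,
        rise_fraction=rise,
        site_offsets_px=offsets,
        site_weights=balanced_site_weights(n_sites),
    )


def make_truth(cells, events=(), optical=None, scene=None, seed=0):
    return GroundTruth(
        cells=tuple(cells),
        events=tuple(events),
        seed=seed,
        optical=optical or OpticalConfig(field_size=(256, 256)),
        scene=scene or SceneConfig(n_cells=0),
    )


def make_series(track_id, values, dt=1.0, channel="rku"):
    """RoughnessSeries with one populated channel and everything valid."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    other = np.zeros(n)
    return RoughnessSeries(
        track_id=track_id,
        times_min=np.arange(n) * dt,
        rq=np.ones(n),
        rsk=values if channel == "rsk" else other,
        rku=values if channel == "rku" else other,
        n_px=np.full(n, 500),
        valid=np.ones(n, dtype=bool),
    )
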