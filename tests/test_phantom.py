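"""Phantom generator: optics, envelope, scene sampling and rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holorough.phantom import (
    OpticalConfig,
    PlacementError,
    SceneConfig,
    balanced_site_weights,
    event_envelope,
    phase_shift,
    render_frame,
    sample_phantoms,
    simulate,
    thickness_from_phase,
)

from conftest import make_cell, make_event, make_truth


class TestPhaseShift:
    @pytest.mark.parametrize(
        "wavelength,n,x,expected",
        [
            (500.0, 1.0, 500.0, 2 * math.pi),  # one full cycle when x = lambda
            (650.0, 1.37, 0.0, 0.0),
            (650.0, 1.37, 1000.0, 13.243021339747745),  # hand evaluation
        ],
    )
    def test_known_values(self, wavelength, n, x, expected):
        assert phase_shift(wavelength, n, x) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_wavelength(self):
        with pytest.raises(ValueError):
            phase_shift(0.0, 1.37, 100.0)
        with pytest.raises(ValueError):
            phase_shift(-635.0, 1.37, 100.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        wavelength=st.floats(100.0, 2000.0),
        n=st.floats(0.01, 3.0),
        x=st.floats(0.0, 1e5),
    )
    def test_round_trip_recovers_thickness(self, wavelength, n, x):
        phi = phase_shift(wavelength, n, x)
        assert thickness_from_phase(wavelength, n, phi) == pytest.approx(
            x, rel=1e-12, abs=1e-12
        )

    def test_monotone_in_thickness(self):
        xs = np.linspace(0.0, 2000.0, 50)
        phis = phase_shift(635.0, 1.37, xs)
        assert np.all(np.diff(phis) > 0)


class TestEventEnvelope:
    def test_zero_outside_support_and_closed_at_end(self):
        ev = make_event(onset=15.0, duration=7.2)
        assert event_envelope(14.999, ev) == 0.0
        assert event_envelope(0.0, ev) == 0.0
        assert event_envelope(15.0 + 7.2, ev) == 0.0
        assert event_envelope(60.0, ev) == 0.0

    def test_single_interior_maximum_of_one_at_documented_peak_time(self):
        # rise fraction 0.55 of a 7.2-min event starting at 15 min peaks
        # near 19 min
        ev = make_event(onset=15.0, duration=7.2, rise=0.55)
        t = np.linspace(14.0, 23.0, 9001)
        env = event_envelope(t, ev)
        assert env.max() == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(env)] == pytest.approx(15.0 + 0.55 * 7.2, abs=2e-3)
        assert abs(t[np.argmax(env)] - 19.0) < 0.05
        # unimodal: increases then decreases
        d = np.diff(env[(t > 15.0) & (t < 22.2)])
        switches = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert switches <= 1

    def test_envelope_bounded_and_continuous(self):
        ev = make_event(onset=5.0, duration=4.0, rise=0.3)
        t = np.linspace(0.0, 15.0, 30001)
        env = event_envelope(t, ev)
        assert np.all((env >= 0.0) & (env <= 1.0))
        assert np.max(np.abs(np.diff(env))) < 2e-3  # no jumps at this sampling

    def test_zero_rise_fraction_peaks_at_onset(self):
        ev = make_event(onset=0.0, duration=5.0, rise=0.0)
        assert event_envelope(0.0, ev) == pytest.approx(1.0)
        assert event_envelope(2.5, ev) < 1.0


class TestSitePattern:
    def test_balanced_weights_cancel_third_moments(self):
        for n in (2, 3, 4, 5, 7):
            w = balanced_site_weights(n)
            assert sum(x**3 for x in w) == pytest.approx(0.0, abs=1e-12)

    def test_single_site_is_positive(self):
        assert balanced_site_weights(1) == (1.0,)


class TestSamplePhantoms:
    def test_zero_cells(self, small_optical):
        truth = sample_phantoms(small_optical, SceneConfig(n_cells=0), seed=1)
        assert truth.cells == () and truth.events == ()

    def test_all_quiescent_scene_has_no_events(self, small_optical):
        scene = SceneConfig(n_cells=12, fate_mix={"quiescent": 1.0})
        truth = sample_phantoms(small_optical, scene, seed=1)
        assert len(truth.cells) == 12
        assert truth.events == ()
        assert all(c.fate == "quiescent" for c in truth.cells)

    def test_fate_mixture_counts_are_deterministic(self, small_optical):
        scene = SceneConfig(n_cells=8, fate_mix={"normal": 0.5, "quiescent": 0.5})
        truth = sample_phantoms(small_optical, scene, seed=3)
        fates = sorted(c.fate for c in truth.cells)
        assert fates == ["normal"] * 4 + ["quiescent"] * 4
        assert len(truth.events) == 4  # one per normal-fate cell

    def test_same_seed_identical_ground_truth(self, small_optical):
        scene = SceneConfig(n_cells=10)
        a = sample_phantoms(small_optical, scene, seed=7)
        b = sample_phantoms(small_optical, scene, seed=7)
        assert a == b

    def test_footprints_do_not_overlap(self, small_optical):
        scene = SceneConfig(n_cells=10)
        truth = sample_phantoms(small_optical, scene, seed=2)
        cells = truth.cells
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = math.hypot(
                    cells[i].centroid_rc[0] - cells[j].centroid_rc[0],
                    cells[i].centroid_rc[1] - cells[j].centroid_rc[1],
                )
                assert d > cells[i].bounding_radius_px + cells[j].bounding_radius_px

    def test_capacity_error_names_achieved_count(self):
        tiny = OpticalConfig(field_size=(64, 64))
        with pytest.raises(PlacementError) as exc:
            sample_phantoms(tiny, SceneConfig(n_cells=30), seed=1)
        assert exc.value.achieved < 30
        assert str(exc.value.achieved) in str(exc.value)

    def test_event_sites_inside_footprint(self, small_optical):
        scene = SceneConfig(n_cells=6, fate_mix={"normal": 1.0})
        truth = sample_phantoms(small_optical, scene, seed=4)
        for ev in truth.events:
            cell = next(c for c in truth.cells if c.cell_id == ev.cell_id)
            a, b = cell.semi_axes_px
            for dr, dc in ev.site_offsets_px:
                assert (dr / a) ** 2 + (dc / b) ** 2 <= 1.0


class TestRenderFrame:
    def test_empty_truth_no_noise_renders_zeros(self, small_optical):
        scene = SceneConfig(n_cells=0, background_sigma_nm=0.0)
        truth = make_truth([], optical=small_optical, scene=scene)
        frame = render_frame(truth, 0.0)
        assert frame.shape == small_optical.field_size
        assert np.all(frame == 0.0)

    def test_noiseless_cell_is_exactly_its_dome(self, small_optical):
        cell = make_cell(peak=300.0, fluct=0.0)
        truth = make_truth([cell], optical=small_optical,
                           scene=SceneConfig(n_cells=0, background_sigma_nm=0.0))
        frame = render_frame(truth, 0.0)
        # centre value equals peak thickness; outside footprint is zero
        assert frame[128, 128] == pytest.approx(300.0, rel=1e-6)
        assert frame[128, 128 + 16] == 0.0
        # analytic paraboloidal dome at an interior pixel
        u2 = (8.0 / 15.0) ** 2
        assert frame[136, 128] == pytest.approx(300.0 * (1 - u2), rel=1e-9)

    def test_event_raises_fourth_standardised_moment(self, small_optical):
        """A perturbation at the envelope peak fattens the tails of the
        intra-cell height distribution: the detection premise."""
        cell = make_cell(fluct=4.0, fate="normal")
        ev = make_event(onset=10.0, duration=6.0)
        scene = SceneConfig(n_cells=0, background_sigma_nm=0.0)
        mask = cell.footprint_mask(small_optical.field_size)

        def rku_at_peak(with_event):
            truth = make_truth([cell], [ev] if with_event else [],
                               optical=small_optical, scene=scene)
            rng = np.random.default_rng(0)
            frame = render_frame(truth, ev.peak_time_min, rng=rng)
            z = frame[mask]
            z = z - z.mean()
            return np.mean(z**4) / np.mean(z**2) ** 2

        assert rku_at_peak(True) > rku_at_peak(False)

    def test_kurtosis_monotone_in_event_amplitude(self, small_optical):
        from holorough.roughness import descriptors, detrend

        cell = make_cell(fluct=4.0, fate="normal")
        scene = SceneConfig(n_cells=0, background_sigma_nm=0.0)
        mask = cell.footprint_mask(small_optical.field_size)
        rows, cols = np.nonzero(mask)
        kurts = []
        for amp in (0.0, 40.0, 80.0, 140.0):
            ev = make_event(amplitude=amp, onset=10.0, duration=6.0)
            truth = make_truth([cell], [ev], optical=small_optical, scene=scene)
            frame = render_frame(truth, ev.peak_time_min,
                                 rng=np.random.default_rng(0))
            resid = detrend(rows, cols, frame[rows, cols])
            kurts.append(descriptors(resid)[2])
        assert all(b >= a for a, b in zip(kurts, kurts[1:]))
        assert kurts[-1] > kurts[0] + 1.0

    def test_dying_cell_dome_collapses_monotonically(self, small_optical):
        cell = make_cell(fate="dying", death_time=10.0, fluct=0.0)
        truth = make_truth([cell], optical=small_optical,
                           scene=SceneConfig(n_cells=0, background_sigma_nm=0.0))
        heights = [render_frame(truth, t)[128, 128] for t in (5, 10, 12, 15, 20)]
        assert heights[0] == heights[1] == pytest.approx(300.0, rel=1e-6)
        assert heights[1] > heights[2] > heights[3] > heights[4]


class TestSimulate:
    def test_frame_count_fencepost(self):
        opt = OpticalConfig(field_size=(96, 96), duration_min=60.0)
        stack, _ = simulate(opt, SceneConfig(n_cells=0), seed=0)
        assert stack.n_frames == 61
        assert stack.timestamps_min[0] == 0.0 and stack.timestamps_min[-1] == 60.0

    def test_zero_duration_single_frame(self):
        opt = OpticalConfig(field_size=(96, 96), duration_min=0.0)
        stack, _ = simulate(opt, SceneConfig(n_cells=0), seed=0)
        assert stack.n_frames == 1

    def test_bit_identical_for_same_seed(self, small_optical):
        opt = OpticalConfig(field_size=(128, 128), duration_min=10.0)
        scene = SceneConfig(n_cells=3)
        a, ta = simulate(opt, scene, seed=11)
        b, tb = simulate(opt, scene, seed=11)
        assert np.array_equal(a.data, b.data)
        assert ta == tb

    def test_different_seeds_differ(self):
        opt = OpticalConfig(field_size=(128, 128), duration_min=5.0)
        scene = SceneConfig(n_cells=3)
        a, _ = simulate(opt, scene, seed=1)
        b, _ = simulate(opt, scene, seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_adding_a_cell_preserves_other_cells_noise(self):
        """Per-cell child streams: cell 0's pixels are identical whether or
        not more cells exist elsewhere in the field."""
        opt = OpticalConfig(field_size=(200, 200), duration_min=5.0,
                            )
        scene1 = SceneConfig(n_cells=1, fate_mix={"quiescent": 1.0},
                             background_sigma_nm=0.0)
        scene2 = SceneConfig(n_cells=2, fate_mix={"quiescent": 1.0},
                             background_sigma_nm=0.0)
        a, ta = simulate(opt, scene1, seed=5)
        b, tb = simulate(opt, scene2, seed=5)
        assert ta.cells[0] == tb.cells[0]
        mask = ta.cells[0].footprint_mask((200, 200))
        assert np.array_equal(a.data[3][mask], b.data[3][mask])
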