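"""Synthetic-movie generator: spike trains, rendering, presets, ground truth."""

import numpy as np
import pytest

from calfluor.exceptions import ParameterError, PlacementError
from calfluor.simulate import (
    SimParams,
    generate_spike_trains,
    preset,
    read_ground_truth,
    render_movie,
    simulate,
    write_ground_truth,
)
from conftest import small_params


class TestSpikeTrains:
    def test_full_synchrony_gives_identical_trains(self):
        p = small_params(p_sync=1.0, rate_independent_hz=0.0, rate_network_hz=0.1)
        trains = generate_spike_trains(p)
        assert len(trains) == p.n_cells
        assert all(t == trains[0] for t in trains)
        assert len(trains[0]) > 0

    def test_zero_rates_give_empty_trains(self):
        p = small_params(rate_independent_hz=0.0, rate_network_hz=0.0)
        assert generate_spike_trains(p) == [[] for _ in range(p.n_cells)]

    def test_trains_sorted_unique_in_range(self):
        p = small_params(rate_independent_hz=0.1, rate_network_hz=0.1, n_frames=60)
        for train in generate_spike_trains(p):
            assert train == sorted(set(train))
            assert all(0 <= f < 60 for f in train)

    def test_network_participation_fraction_matches_p_sync(self):
        # With no independent events, every spiking frame is a network event;
        # the mean per-event participation should estimate p_sync = 0.6.
        fractions = []
        for seed in range(20):
            p = SimParams(
                n_cells=50,
                n_frames=150,
                frame_period_s=1.0,
                rate_independent_hz=0.0,
                rate_network_hz=0.05,
                p_sync=0.6,
                seed=seed,
            )
            trains = generate_spike_trains(p)
            counts = np.zeros(150)
            for train in trains:
                counts[train] += 1
            event_frames = counts > 0
            if event_frames.any():
                fractions.append(np.mean(counts[event_frames]) / p.n_cells)
        assert abs(np.mean(fractions) - 0.6) <= 0.1

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            small_params(rate_independent_hz=-1.0)
        with pytest.raises(ParameterError):
            small_params(rate_network_hz=float("nan"))


class TestRenderMovie:
    def test_no_cells_gives_pure_baseline(self):
        p = small_params(n_cells=0)
        movie, truth = simulate(p)
        assert movie.frames.min() == movie.frames.max() == round(p.baseline_level)
        assert truth.cell_masks.max() == 0
        assert truth.spike_times == []

    def test_center_pixel_peaks_rise_frames_after_spike(self):
        p = small_params(
            n_cells=1,
            rise_frames=3,
            rate_independent_hz=0.0,
            rate_network_hz=0.0,
            bleach_tau_s=float("inf"),
        )
        spike_frame = 10
        movie, truth = render_movie(p, [[spike_frame]])
        r, c = truth.cell_centers[0]
        trace = movie.frames[:, r, c].astype(float)
        assert int(np.argmax(trace)) == spike_frame + p.rise_frames

    def test_determinism_byte_identical(self):
        p = small_params(shot_noise=True, read_noise_sd=1.5, seed=42)
        m1, t1 = simulate(p)
        m2, t2 = simulate(p)
        assert np.array_equal(m1.frames, m2.frames)
        assert t1.spike_times == t2.spike_times
        assert t1.cell_centers == t2.cell_centers

    def test_background_outside_masks_follows_bleach(self):
        p = small_params(bleach_tau_s=500.0)
        movie, truth = simulate(p)
        outside = truth.cell_masks == 0
        expected = p.baseline_level * np.exp(-movie.times_s / p.bleach_tau_s)
        for t in range(0, movie.n_frames, 7):
            measured = movie.frames[t][outside].mean()
            assert abs(measured - expected[t]) <= 0.5

    def test_placement_respects_min_distance(self, clean_movie):
        _, truth = clean_movie
        centers = np.array(truth.cell_centers)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.hypot(*(centers[i] - centers[j])) >= 20.0

    def test_crowded_field_raises_placement_error(self):
        with pytest.raises(PlacementError, match="min_center_distance_px"):
            simulate(small_params(n_cells=40, field_height_px=64, field_width_px=64))

    def test_death_cells_drop_permanently(self):
        p = small_params(
            death_fraction=0.4,
            n_frames=40,
            death_dt_frames_distribution=((8, 1.0),),
            rate_independent_hz=0.0,
            rate_network_hz=0.0,
        )
        movie, truth = simulate(p)
        dying = [(c, ev) for c, ev in enumerate(truth.death_events) if ev is not None]
        assert len(dying) == 2  # 40% of 5
        for cell, (influx, efflux) in dying:
            assert efflux - influx == 8
            r, c = truth.cell_centers[cell]
            trace = movie.frames[:, r, c].astype(float)
            pre = trace[influx - 1] - p.baseline_level
            # elevated plateau between influx and efflux, then a permanent fall
            assert trace[influx:efflux + 1].min() > trace[influx - 1]
            post = trace[efflux + 1 :] - p.baseline_level
            assert post.max() <= 0.1 * pre + 1.0  # quantization slack


class TestPresets:
    def test_long_term_regime(self):
        p = preset("long_term_10h")
        assert p.n_frames == 61 and p.frame_period_s == 600.0
        assert p.n_frames * p.frame_period_s == 36600  # covers t = 0 .. 10 h

    def test_fast_session_regime(self):
        p = preset("fast_session_150s")
        assert p.n_frames == 150 and p.frame_period_s == 1.0

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ParameterError, match="long_term_10h"):
            preset("bogus")


class TestGroundTruth:
    def test_death_dt_distribution_must_sum_to_one(self):
        with pytest.raises(ParameterError, match="sum"):
            small_params(death_dt_frames_distribution=((5, 0.5), (10, 0.6)))

    def test_sidecar_round_trip(self, tmp_path, clean_movie):
        _, truth = clean_movie
        write_ground_truth(truth, tmp_path)
        back = read_ground_truth(tmp_path)
        assert [tuple(c) for c in back["cell_centers"]] == truth.cell_centers
        assert back["spike_times"] == truth.spike_times
        assert np.array_equal(back["cell_masks"], truth.cell_masks)

    def test_placement_seed_fixes_geometry_across_activity_seeds(self):
        a = simulate(small_params(seed=1, placement_seed=99))[1]
        b = simulate(small_params(seed=2, placement_seed=99))[1]
        assert a.cell_centers == b.cell_centers
        assert a.spike_times != b.spike_times
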