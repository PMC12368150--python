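"""Generator contracts: geometry, determinism, track/image consistency."""

import numpy as np
import pytest

from myxostream import SwarmConfig, simulate_swarm
from myxostream.synthetic import (
    AggregateSpec,
    StreamLane,
    default_stream_lanes,
    lane_mask,
    render_frame,
)


def small_config(**kw) -> SwarmConfig:
    base = dict(image_size=120, n_frames=40, n_cells=30, rng_seed=1)
    base.update(kw)
    return SwarmConfig(**base)


class TestSimulateSwarm:
    def test_static_limit(self):
        """Zero speed and zero angular noise: frames are identical and no
        stream truth exists."""
        cfg = small_config(
            scenario="random", speed_um_per_min=0.0, orientation_jitter_rad=0.0,
            noise_sd=0.0,
        )
        movie = simulate_swarm(cfg)
        assert not movie.truth_stream_masks.any()
        assert all(
            np.array_equal(movie.stack.frames[0], f) for f in movie.stack.frames
        )

    def test_truth_mask_follows_lane_activity(self):
        lane = StreamLane([(0, 60), (120, 60)], 20, 15, 35)
        cfg = small_config(scenario="streams", stream_lanes=[lane])
        movie = simulate_swarm(cfg)
        assert not movie.truth_stream_masks[10].any()
        expected = lane_mask(lane, (120, 120))
        assert np.array_equal(movie.truth_stream_masks[25], expected)
        # horizontal lane of full width: a rectangle of rows within width/2
        assert expected[60, :].all() and not expected[80, :].any()

    def test_seed_changes_tracks_not_geometry(self):
        lane = StreamLane([(0, 60), (120, 60)], 20, 12, 39)
        movies = [
            simulate_swarm(small_config(scenario="streams", stream_lanes=[lane], rng_seed=s))
            for s in (1, 2)
        ]
        assert np.array_equal(movies[0].truth_stream_masks, movies[1].truth_stream_masks)
        assert not movies[0].tracks[["x_px", "y_px"]].equals(movies[1].tracks[["x_px", "y_px"]])
        for mv in movies:
            # speed estimated from tracks over the full-speed (post-onset) phase
            t = mv.tracks[mv.tracks.frame >= 12].sort_values(["cell_id", "frame"])
            steps = t.groupby("cell_id")[["x_px", "y_px"]].diff().dropna()
            speeds = np.hypot(steps.x_px, steps.y_px) * mv.config.um_per_px
            mean_speed = speeds[speeds > 0].mean()
            assert abs(mean_speed - mv.config.speed_um_per_min) < 0.1 * mv.config.speed_um_per_min

    def test_determinism(self):
        a = simulate_swarm(small_config(scenario="streams"))
        b = simulate_swarm(small_config(scenario="streams"))
        assert np.array_equal(a.stack.frames, b.stack.frames)
        assert a.tracks.equals(b.tracks)
        assert np.array_equal(a.truth_stream_masks, b.truth_stream_masks)

    def test_tracked_centroids_are_bright(self):
        movie = simulate_swarm(small_config(scenario="random", n_cells=15))
        for t in (0, 20, 39):
            frame = movie.stack.frames[t]
            med = np.median(frame)
            rows = movie.tracks[movie.tracks.frame == t]
            ix = np.clip(rows.x_px.round().astype(int), 0, 119)
            iy = np.clip(rows.y_px.round().astype(int), 0, 119)
            assert (frame[iy, ix] > med).all()

    def test_lane_brighter_than_background(self):
        cfg = small_config(scenario="streams",
                           stream_lanes=[StreamLane([(0, 60), (120, 60)], 20, 10, 39)])
        movie = simulate_swarm(cfg)
        for t in (15, 30):
            mask = movie.truth_stream_masks[t]
            frame = movie.stack.frames[t].astype(float)
            assert frame[mask].mean() > frame[~mask].mean()

    def test_tracks_stay_in_frame_and_contiguous(self):
        movie = simulate_swarm(small_config(scenario="streams"))
        t = movie.tracks
        assert t.x_px.between(0, 119).all() and t.y_px.between(0, 119).all()
        for _, g in t.groupby("cell_id"):
            assert np.array_equal(np.sort(g.frame.values), np.arange(40))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_frames=20),
            dict(scenario="nope"),
            dict(scenario="streams",
                 stream_lanes=[StreamLane([(0, 60), (300, 60)], 20, 0, 10)]),
            dict(scenario="aggregates_only",
                 aggregate_events=[AggregateSpec((5, 5), 20, 0)]),
            dict(scenario="aggregates_only",
                 aggregate_events=[AggregateSpec((60, 60), 10, 100)]),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_geometry_covering_frame_rejected(self):
        cfg = small_config(
            scenario="streams",
            stream_lanes=[StreamLane([(0, 60), (120, 60)], 300, 0, 39)],
        )
        with pytest.raises(ValueError, match="background"):
            simulate_swarm(cfg)

    def test_default_lanes_inside_frame(self):
        for lane in default_stream_lanes(400, 310):
            assert lane_mask(lane, (400, 400)).any()


class TestRenderFrame:
    def test_no_agents_no_noise_equals_background(self):
        cfg = small_config(noise_sd=0.0)
        bg = np.full((120, 120), 700.0)
        frame = render_frame(np.empty((0, 3)), bg, cfg)
        assert np.array_equal(frame, bg.astype(np.uint16))

    def test_rotation_symmetry(self):
        """A rod at 90 degrees is the 90-degree rotation of a rod at 0."""
        cfg = small_config(noise_sd=0.0, image_size=121, n_frames=40)
        bg = np.zeros((121, 121))
        f0 = render_frame([[60, 60, 0.0]], bg, cfg).astype(int)
        f90 = render_frame([[60, 60, np.pi / 2]], bg, cfg).astype(int)
        assert np.abs(np.rot90(f0) - f90).max() <= 1

    def test_kernel_integral(self):
        """Integrated intensity above background matches the kernel sum."""
        cfg = small_config(noise_sd=0.0)
        bg = np.zeros((120, 120))
        frame = render_frame([[60.0, 60.0, 0.3]], bg, cfg)
        # independent kernel sum over the full frame
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        dx, dy = xx - 60.0, yy - 60.0
        u = dx * np.cos(0.3) + dy * np.sin(0.3)
        v = -dx * np.sin(0.3) + dy * np.cos(0.3)
        sl = cfg.cell_length_px / 4.0
        sw = max(cfg.cell_width_px / 4.0, 0.4)
        expected = cfg.cell_amplitude * np.exp(-(u**2 / (2 * sl**2) + v**2 / (2 * sw**2)))
        assert abs(frame.sum() - expected.sum()) / expected.sum() < 0.02

    def test_agents_outside_frame_clipped(self):
        cfg = small_config(noise_sd=0.0)
        bg = np.zeros((120, 120))
        frame = render_frame([[-2.0, 60.0, 0.0], [500.0, 500.0, 0.0]], bg, cfg)
        assert frame[:, :3].sum() > 0  # partial rod rendered at the edge
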