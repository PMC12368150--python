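"""Aggregate detection, region partition, and stream proportions."""

import numpy as np
import pytest

from myxostream import (
    AggregateEvent,
    SwarmConfig,
    detect_aggregates,
    equalize,
    make_partition,
    paired_comparison,
    persistence_stack,
    simulate_swarm,
    stream_proportions,
)
from myxostream.synthetic import AggregateSpec


def disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestDetectAggregates:
    def test_onset_recovered_from_synthetic_movie(self):
        cfg = SwarmConfig(
            image_size=120, n_frames=40, n_cells=40, scenario="aggregates_only",
            aggregate_events=[AggregateSpec((60, 60), 10, 18)], rng_seed=5,
        )
        movie = simulate_swarm(cfg)
        ps = equalize(persistence_stack(movie.stack))
        events = detect_aggregates(ps.frames, intensity_min=0.99, area_min_px=25)
        assert len(events) == 1
        # persistence frame k is centered on input frame k+2
        onset_input_frame = events[0].onset_frame + 2
        assert 14 <= onset_input_frame <= 28
        cx, cy = events[0].centroid_px
        assert abs(cx - 60) <= 3 and abs(cy - 60) <= 3

    def test_no_pixels_above_threshold(self, rng):
        frames = rng.random((15, 40, 40)) * 0.5
        assert detect_aggregates(frames, intensity_min=0.9) == []

    def test_two_disjoint_disks(self):
        frames = np.zeros((15, 100, 100))
        d1 = disk_mask((100, 100), 25, 30, 8)
        d2 = disk_mask((100, 100), 70, 65, 8)
        frames[3:, d1] = 1.0
        frames[3:, d2] = 1.0
        events = detect_aggregates(frames, 0.5, area_min_px=25, persistence_min_frames=10)
        assert len(events) == 2
        centroids = sorted((round(e.centroid_px[0]), round(e.centroid_px[1])) for e in events)
        assert abs(centroids[0][0] - 25) <= 3 and abs(centroids[0][1] - 30) <= 3
        assert abs(centroids[1][0] - 70) <= 3 and abs(centroids[1][1] - 65) <= 3

    def test_transient_blob_not_reported(self):
        frames = np.zeros((15, 60, 60))
        frames[4:8, disk_mask((60, 60), 30, 30, 6)] = 1.0  # lives 4 < 10 frames
        assert detect_aggregates(frames, 0.5) == []


class TestMakePartition:
    def test_annulus_geometry(self):
        shape = (200, 200)
        ev = AggregateEvent(0.0, disk_mask(shape, 100, 100, 10), (100, 100), 317)
        part = make_partition([ev], 0, shape, dilation_px=20)
        area = part.s_band.sum()
        expected = np.pi * (30**2 - 10**2)
        assert abs(area - expected) / expected < 0.05
        # band is an annulus between radii 10 and 30
        ring = disk_mask(shape, 100, 100, 30) & ~disk_mask(shape, 100, 100, 10)
        assert (part.s_band == ring).mean() > 0.99

    def test_edge_aggregate_band_clipped(self):
        shape = (100, 100)
        ev = AggregateEvent(0.0, disk_mask(shape, 5, 50, 8), (5, 50), 0)
        part = make_partition([ev], 0, shape)
        assert part.s_band.any()
        assert not (part.s_band & part.s_aggregate).any()

    def test_two_close_aggregates_stay_disjoint(self):
        shape = (150, 150)
        m1 = disk_mask(shape, 60, 75, 6)
        m2 = disk_mask(shape, 81, 75, 6)  # 21 px apart: dilations overlap
        events = [
            AggregateEvent(0.0, m1, (60, 75), int(m1.sum())),
            AggregateEvent(0.0, m2, (81, 75), int(m2.sum())),
        ]
        part = make_partition(events, 0, shape, dilation_px=20)
        # brute-force set checks
        assert not (part.s_band & part.s_aggregate).any()
        assert not (part.s_band & part.s_outside).any()
        assert not (part.s_aggregate & part.s_outside).any()
        # outside excludes both dilation rings
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk as disk_selem

        both_dil = binary_dilation(m1 | m2, structure=disk_selem(20))
        assert not (part.s_outside & both_dil).any()
        # completeness: the three regions plus removed other-band pixels tile the frame
        covered = part.s_aggregate | part.s_band | part.s_outside | both_dil
        assert covered.all()

    def test_unknown_focal_id_errors(self):
        ev = AggregateEvent(0.0, disk_mask((50, 50), 25, 25, 5), (25, 25), 0)
        with pytest.raises(ValueError):
            make_partition([ev], 3, (50, 50))


class TestStreamProportions:
    def _partition(self, shape=(200, 200)):
        ev = AggregateEvent(0.0, disk_mask(shape, 100, 100, 10), (100, 100), 317)
        return make_partition([ev], 0, shape)

    def test_containment_gives_one_and_zero(self):
        part = self._partition()
        stream = part.s_band.copy()
        res = stream_proportions(stream, part)
        assert res.p_band == 1.0 and res.p_outside == 0.0

    def test_empty_stream_gives_zero(self):
        part = self._partition()
        res = stream_proportions(np.zeros((200, 200), bool), part)
        assert res.p_band == 0.0 and res.p_outside == 0.0

    def test_random_stream_null_behavior(self, rng):
        part = self._partition()
        q = 0.3
        stream = rng.random((200, 200)) < q
        res = stream_proportions(stream, part)
        for p, n in ((res.p_band, part.s_band.sum()), (res.p_outside, part.s_outside.sum())):
            se = np.sqrt(q * (1 - q) / n)
            assert abs(p - q) < 3 * se

    def test_empty_region_flagged_undefined(self):
        shape = (60, 60)
        ev = AggregateEvent(0.0, np.ones(shape, bool), (30, 30), 3600)
        part = make_partition([ev], 0, shape)  # no outside left
        res = stream_proportions(np.zeros(shape, bool), part)
        assert not res.defined


class TestPairedComparison:
    def test_shifted_pairs_strongly_significant(self, rng):
        base = rng.uniform(0.2, 0.6, 50)
        shifts = 0.2 + rng.normal(0, 1e-3, 50)
        results = [
            type("R", (), dict(p_band=float(b + s), p_outside=float(b), defined=True))()
            for b, s in zip(base, shifts)
        ]
        cmp = paired_comparison(results)
        assert cmp.n_band_higher == 50 and cmp.n_outside_higher == 0
        assert cmp.p_value < 1e-6

    def test_symmetric_two_pairs(self):
        results = [
            type("R", (), dict(p_band=0.5, p_outside=0.4, defined=True))(),
            type("R", (), dict(p_band=0.4, p_outside=0.5, defined=True))(),
        ]
        cmp = paired_comparison(results)
        assert cmp.n_band_higher == 1 and cmp.n_outside_higher == 1
        assert cmp.t_statistic == pytest.approx(0.0)

    def test_all_ties_reported_with_undefined_t(self):
        results = [
            type("R", (), dict(p_band=0.3, p_outside=0.3, defined=True))()
            for _ in range(5)
        ]
        cmp = paired_comparison(results)
        assert cmp.n_ties == 5
        assert np.isnan(cmp.t_statistic)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            paired_comparison([])
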