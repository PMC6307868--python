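"""Track statistics, classification, directionality, ECDFs and kymographs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import neurorg as ng
from neurorg.errors import KymographError, TrackOutsideMaskError
from neurorg.motility import (
    classify_motility,
    cohort_summary,
    directionality,
    ecdf,
    kymo_readout,
    make_kymograph,
    soma_distance_map,
    temporal_projection,
    track_statistics,
)
from neurorg.segmentation import SegmentationMasks
from neurorg.tracking import Track


def make_track(xy, start=0):
    xy = np.asarray(xy, dtype=float)
    return Track(track_id=0, organelle="PO", frames=np.arange(start, start + len(xy)),
                 xy_um=xy)


class TestTrackStatistics:
    def test_stationary_track_all_zero(self):
        s = track_statistics(make_track([[1.0, 1.0]] * 10), frame_interval=5.0)
        assert s.total_distance == 0 and s.net_distance == 0
        assert s.max_speed == 0 and s.avg_speed == 0
        assert s.motility_class == "static"

    def test_printed_pair_consistency(self):
        # 24 oscillation steps of 0.15 um in a 480 s session: 3.6 um total,
        # average speed 3.6/480 = 0.0075 um/s
        xy = [[0.0, 0.0]]
        x = 0.0
        for i in range(96):
            if i < 24:
                x += 0.15
            xy.append([x, 0.0])
        s = track_statistics(make_track(xy), frame_interval=5.0)
        assert s.total_distance == pytest.approx(3.6)
        assert s.duration_s == pytest.approx(480.0)
        assert s.avg_speed == pytest.approx(0.0075)

    def test_out_and_back(self):
        xy = [[0, 0], [1, 0], [2, 0], [1, 0], [0, 0]]
        s = track_statistics(make_track(xy), frame_interval=5.0)
        assert s.total_distance == pytest.approx(4.0)
        assert s.net_distance == pytest.approx(0.0)

    def test_floor_suppresses_jitter(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 0.02, (50, 2)), axis=0)
        s = track_statistics(make_track(xy), frame_interval=5.0, displacement_floor=0.1)
        assert s.total_distance == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            track_statistics(make_track([[0, 0]]), 5.0)

    @given(st.integers(0, 10_000))
    def test_invariants_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        xy = np.cumsum(rng.normal(0, 0.3, (n, 2)), axis=0)
        s = track_statistics(make_track(xy), frame_interval=5.0)
        s0 = track_statistics(make_track(xy), frame_interval=5.0, displacement_floor=0.0)
        assert s0.total_distance >= s0.net_distance - 1e-9  # triangle inequality
        assert s.max_speed >= 0
        # avg_speed x duration == total_distance (exact identity)
        assert s.avg_speed * s.duration_s == pytest.approx(s.total_distance, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "distance,expected",
        [(0.5, "static"), (1.0, "very_short"), (4.99, "very_short"),
         (5.0, "short"), (9.99, "short"), (10.0, "long"), (12.0, "long")],
    )
    def test_boundaries(self, distance, expected):
        assert classify_motility(distance) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_motility(-0.1)


class TestCohort:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        summaries = [
            track_statistics(
                make_track(np.cumsum(rng.normal(0, 0.3, (20, 2)), axis=0)), 5.0
            )
            for _ in range(40)
        ]
        c = cohort_summary(summaries)
        assert sum(c.class_fractions.values()) == pytest.approx(1.0)

    def test_single_static_track(self):
        c = cohort_summary([track_statistics(make_track([[0, 0]] * 5), 5.0)])
        assert c.class_fractions == {
            "static": 1.0, "very_short": 0.0, "short": 0.0, "long": 0.0
        }

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_ecdf_properties(self):
        x, y = ecdf(np.array([3.0, 1.0, 2.0, 2.0]))
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(y) >= 0)          # nondecreasing
        assert y[-1] == pytest.approx(1.0)      # reaches 1


class TestDirectionality:
    @staticmethod
    def masks_with_corridor():
        soma = np.zeros((64, 256), bool)
        soma[22:42, 10:30] = True               # soma block on the left
        neurite = np.zeros((64, 256), bool)
        neurite[28:36, 30:250] = True           # straight corridor to the right
        return SegmentationMasks(soma, neurite, (32.0, 20.0))

    def test_signed_displacement(self):
        masks = self.masks_with_corridor()
        ps = 0.08
        dmap = soma_distance_map(masks, ps)
        out = make_track([[40 * ps, 32 * ps], [(40 + 37) * ps, 32 * ps]])  # ~3 um out
        back = make_track([[(40 + 37) * ps, 32 * ps], [40 * ps, 32 * ps]])
        loop = make_track([[40 * ps, 32 * ps], [60 * ps, 32 * ps], [40 * ps, 32 * ps]])
        assert directionality(out, masks, ps, dmap) == pytest.approx(3.0, abs=0.15)
        assert directionality(back, masks, ps, dmap) == pytest.approx(-3.0, abs=0.15)
        assert directionality(loop, masks, ps, dmap) == pytest.approx(0.0, abs=0.05)

    def test_outside_mask_raises(self):
        masks = self.masks_with_corridor()
        t = make_track([[0.0, 0.0], [0.1, 0.0]])
        with pytest.raises(TrackOutsideMaskError):
            directionality(t, masks, 0.08)


class TestProjectionAndKymograph:
    def test_temporal_projection_sum(self):
        stack = np.stack([np.full((8, 8), 3.0), np.full((8, 8), 4.0)])
        assert np.all(temporal_projection(stack) == 7.0)

    def test_static_spot_vertical_line(self):
        t, h, w = 20, 32, 128
        stack = np.zeros((t, h, w))
        stack[:, 16, 60] = 100.0
        polyline = np.array([[16.0, 5.0], [16.0, 120.0]])
        kymo = make_kymograph(stack, polyline, width=5)
        assert kymo.data.shape[0] == t
        cols = kymo.data.argmax(axis=1)
        assert np.all(cols == cols[0])  # constant position over time

    def test_moving_spot_slope(self):
        t, h, w = 30, 32, 200
        stack = np.zeros((t, h, w))
        v_px = 2.0  # px per frame along the path
        for k in range(t):
            stack[k, 16, int(20 + v_px * k)] = 100.0
        kymo = make_kymograph(stack, np.array([[16.0, 0.0], [16.0, 199.0]]), width=3)
        cols = kymo.data.argmax(axis=1)
        slope = np.polyfit(np.arange(t), cols, 1)[0]
        assert slope == pytest.approx(v_px, abs=0.1)

    def test_offset_spot_captured_by_width(self):
        stack = np.zeros((3, 32, 64))
        stack[:, 18, 30] = 50.0  # 2 px off the polyline row 16
        kymo = make_kymograph(stack, np.array([[16.0, 5.0], [16.0, 60.0]]), width=5)
        assert kymo.data.max() >= 49.0

    def test_polyline_exits_frame_raises(self):
        with pytest.raises(KymographError):
            make_kymograph(np.zeros((2, 16, 16)), np.array([[8.0, -5.0], [8.0, 30.0]]), 3)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            make_kymograph(np.zeros((2, 16, 16)), np.array([[8.0, 2.0], [8.0, 12.0]]), 4)


class TestKymoReadout:
    def test_vertical_segment_zero_velocity(self):
        total, mean_v, segs = kymo_readout(np.array([[0, 10], [20, 10]]), 0.08, 5.0)
        assert total == 0.0 and segs[0] == 0.0

    def test_arithmetic_example(self):
        # 20 rows (100 s), 25 cols (2.0 um at 0.08): 0.02 um/s
        total, mean_v, segs = kymo_readout(np.array([[0, 0], [20, 25]]), 0.08, 5.0)
        assert total == pytest.approx(2.0)
        assert segs[0] == pytest.approx(0.02)

    def test_two_segments_sum(self):
        total, _, segs = kymo_readout(
            np.array([[0, 0], [10, 10], [20, 4]]), 0.08, 5.0
        )
        assert total == pytest.approx((10 + 6) * 0.08)
        assert len(segs) == 2

    def test_zero_row_step_raises(self):
        with pytest.raises(ValueError):
            kymo_readout(np.array([[5, 0], [5, 10]]), 0.08, 5.0)


class TestKymoVsTrackAgreement:
    def test_constant_velocity_agreement(self):
        # simulated constant-velocity spot: kymograph readout within one
        # pixel-quantization unit of track_statistics max speed
        t, h, w = 25, 32, 256
        ps, dt = 0.08, 5.0
        stack = np.zeros((t, h, w), dtype=float)
        v_umps = 0.1
        v_px = v_umps * dt / ps  # 6.25 px/frame
        xs = 20 + v_px * np.arange(t)
        rr, cc = np.mgrid[:h, :w].astype(float)
        for k in range(t):
            stack[k] = 900 * np.exp(-((rr - 16) ** 2 + (cc - xs[k]) ** 2) / (2 * 1.9**2))
        kymo = make_kymograph(stack, np.array([[16.0, 0.0], [16.0, 255.0]]), width=5)
        cols = kymo.data.argmax(axis=1)
        total, mean_v, _ = kymo_readout(
            np.array([[0, cols[0]], [t - 1, cols[-1]]]), ps, dt
        )
        track = make_track(np.stack([xs * ps, np.full(t, 16 * ps)], axis=1))
        s = track_statistics(track, dt)
        quantum = ps / dt  # one pixel per frame interval
        assert abs(mean_v - s.max_speed) <= quantum
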