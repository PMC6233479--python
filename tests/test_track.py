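import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohp.core import Calibration, OhpError
from ohp.detect import Spot
from ohp.track import (
    KalmanState,
    Track,
    TrackingParams,
    classify_direction,
    compute_track_features,
    kalman_predict,
    link_tracks,
)

NO_DURATION_FILTER = TrackingParams(min_duration_s=0.0)


def _spot(frame, x_um, y_um=5.0, quality=100.0):
    return Spot(frame=frame, x_um=x_um, y_um=y_um, quality=quality, radius_um=0.8)


def _by_frame(spots, n_frames):
    frames = [[] for _ in range(n_frames)]
    for s in spots:
        frames[s.frame].append(s)
    return frames


class TestLinkTracks:
    def test_single_moving_spot_gives_one_track(self, cal):
        spots = [_spot(f, 2.0 + 0.5 * f) for f in range(20)]
        tracks = link_tracks(_by_frame(spots, 20), TrackingParams(), cal)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 20

    def test_jump_beyond_search_radius_splits_track(self, cal):
        # 3 um jump against a 2 um search radius cannot be linked.
        spots = [_spot(f, 1.0) for f in range(10)] + [
            _spot(f, 4.0) for f in range(10, 20)
        ]
        tracks = link_tracks(_by_frame(spots, 20), NO_DURATION_FILTER, cal)
        assert len(tracks) == 2

    def test_gap_of_two_frames_is_closed(self, cal):
        spots = [_spot(f, 1.0 + 0.1 * f) for f in range(20) if f not in (8, 9)]
        tracks = link_tracks(_by_frame(spots, 20), TrackingParams(max_frame_gap=2), cal)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 18

    def test_gap_of_three_frames_terminates_track(self, cal):
        spots = [_spot(f, 1.0 + 0.1 * f) for f in range(24) if f not in (10, 11, 12)]
        tracks = link_tracks(
            _by_frame(spots, 24), TrackingParams(max_frame_gap=2, min_duration_s=0), cal
        )
        assert len(tracks) == 2

    def test_zero_spots_zero_tracks(self, cal):
        assert link_tracks([[] for _ in range(10)], TrackingParams(), cal) == []

    def test_two_parallel_organelles_stay_separate(self, cal):
        spots = []
        for f in range(15):
            spots.append(_spot(f, 2.0 + 0.3 * f, y_um=3.0))
            spots.append(_spot(f, 2.0 + 0.3 * f, y_um=8.0))
        tracks = link_tracks(_by_frame(spots, 15), TrackingParams(), cal)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {s.y_um for s in tr.spots}
            assert len(ys) == 1  # no identity switches

    def test_duration_filter_requires_ten_frames_at_defaults(self, cal):
        params = TrackingParams()
        assert params.min_frame_count(cal) == 10
        spots9 = [_spot(f, 1.0 + 0.2 * f) for f in range(9)]
        spots10 = [_spot(f, 1.0 + 0.2 * f) for f in range(10)]
        assert link_tracks(_by_frame(spots9, 9), params, cal) == []
        assert len(link_tracks(_by_frame(spots10, 10), params, cal)) == 1

    def test_deterministic_for_identical_input(self, cal):
        rng = np.random.default_rng(0)
        spots = [
            _spot(f, x, y)
            for f in range(12)
            for x, y in rng.uniform(1, 12, size=(6, 2))
        ]
        a = link_tracks(_by_frame(spots, 12), NO_DURATION_FILTER, cal)
        b = link_tracks(_by_frame(spots, 12), NO_DURATION_FILTER, cal)
        assert [[(s.frame, s.x_um, s.y_um) for s in t.spots] for t in a] == [
            [(s.frame, s.x_um, s.y_um) for s in t.spots] for t in b
        ]

    def test_each_spot_in_at_most_one_track(self, benchmark_run):
        _, _, _, tracks = benchmark_run
        seen = set()
        for tr in tracks:
            for s in tr.spots:
                assert id(s) not in seen
                seen.add(id(s))


class TestKalman:
    def _state(self, x, y):
        return KalmanState(x, y, meas_sigma_um=0.05, process_sigma_um=0.2, init_vel_sigma_um=2.0)

    def test_single_spot_predicts_own_position(self):
        st_ = self._state(3.0, 4.0)
        np.testing.assert_allclose(kalman_predict(st_, 1.0), [3.0, 4.0])

    def test_constant_velocity_extrapolation(self):
        st_ = self._state(0.0, 0.0)
        st_.advance(1.0, np.array([1.0, 0.0]))
        pred = kalman_predict(st_, 1.0)
        assert pred[0] == pytest.approx(2.0, abs=0.1)
        assert pred[1] == pytest.approx(0.0, abs=0.05)

    def test_stationary_noisy_sequence_velocity_converges_to_zero(self):
        rng = np.random.default_rng(0)
        st_ = self._state(5.0, 5.0)
        for _ in range(60):
            st_.advance(1.0, np.array([5.0, 5.0]) + rng.normal(0, 0.05, 2))
        speed = math.hypot(st_.state[2], st_.state[3])
        assert speed < 0.05


class TestTrackFeatures:
    def test_hand_computed_straight_track(self, cal):
        track = Track(0, [_spot(f, float(f), 0.0) for f in range(3)])
        ft = compute_track_features(track, cal)
        assert ft.displacement_um == pytest.approx(2.0)
        assert ft.length_um == pytest.approx(2.0)
        assert ft.mean_speed_um_s == pytest.approx(3.3)
        assert ft.sd_speed_um_s == 0.0
        assert ft.angle_rad == pytest.approx(0.0)
        assert ft.direction == "retrograde"
        assert ft.duration_s == pytest.approx(3 / 3.3)

    def test_reversed_track_flips_angle_only(self, cal):
        fwd = Track(0, [_spot(f, float(f), 0.0) for f in range(3)])
        rev = Track(1, [_spot(f, float(2 - f), 0.0) for f in range(3)])
        ft_f = compute_track_features(fwd, cal)
        ft_r = compute_track_features(rev, cal)
        assert ft_r.angle_rad == pytest.approx(math.pi)
        assert ft_r.direction == "anterograde"
        assert ft_r.displacement_um == pytest.approx(ft_f.displacement_um)
        assert ft_r.mean_speed_um_s == pytest.approx(ft_f.mean_speed_um_s)

    def test_l_shaped_track_pythagoras(self, cal):
        track = Track(
            0,
            [_spot(0, 0.0, 0.0), _spot(1, 1.0, 0.0), _spot(2, 1.0, 1.0)],
        )
        ft = compute_track_features(track, cal)
        assert ft.length_um == pytest.approx(2.0)
        assert ft.displacement_um == pytest.approx(math.sqrt(2))

    def test_image_y_axis_is_negated_in_angle(self, cal):
        # Downward in the image (increasing row/y) = negative math angle.
        track = Track(0, [_spot(0, 0.0, 0.0), _spot(1, 1.0, 1.0)])
        ft = compute_track_features(track, cal)
        assert ft.angle_rad == pytest.approx(-math.pi / 4)

    def test_gap_closed_link_speed_is_time_normalized(self, cal):
        # A link spanning 3 frames contributes distance / (3 * dt), once.
        track = Track(
            0, [_spot(0, 0.0), _spot(1, 0.3), _spot(2, 0.6), _spot(5, 1.5)]
        )
        ft = compute_track_features(track, cal)
        dt = cal.frame_interval_s
        expected = np.array([0.3 / dt, 0.3 / dt, 0.9 / (3 * dt)])
        assert ft.mean_speed_um_s == pytest.approx(expected.mean())
        assert ft.max_speed_um_s == pytest.approx(expected.max())

    def test_single_spot_track_is_an_error(self, cal):
        with pytest.raises(OhpError):
            compute_track_features(Track(0, [_spot(0, 1.0)]), cal)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=2,
            max_size=15,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_displacement_never_exceeds_length(self, points):
        cal = Calibration()
        track = Track(0, [_spot(i, x, y) for i, (x, y) in enumerate(points)])
        ft = compute_track_features(track, cal)
        assert ft.displacement_um <= ft.length_um + 1e-9
        assert ft.min_speed_um_s <= ft.median_speed_um_s <= ft.max_speed_um_s
        assert ft.sd_speed_um_s >= 0


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (0.0, "retrograde"),
            (math.pi, "anterograde"),
            (math.pi / 2, "retrograde"),  # closed boundary
            (-math.pi / 2, "retrograde"),
            (math.pi / 2 + 1e-9, "anterograde"),
            (-3 * math.pi / 4, "anterograde"),
        ],
    )
    def test_angle_rule(self, angle, expected):
        assert classify_direction(angle) == expected
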