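"""Linear-motion LAP tracking with Kalman prediction, gap closing,
duration filtering, and per-track kinematic features.

Linking solves, per frame, a rectangular linear assignment problem whose
cost is the squared distance between each live track's Kalman-predicted
position and each candidate spot; links beyond the search radius are
forbidden. Tracks missing for at most ``max_frame_gap`` frames may be
resumed against the predicted position (gap closing); beyond that they
terminate. Tracks shorter than the duration filter are discarded.

Duration counts frames inclusively: duration_s = (last - first + 1) *
frame_interval_s, so the default 3 s filter at 3.3 fps requires 10
consecutive images (ceil(3 * 3.3) = 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ohp.core import Calibration, OhpError
from ohp.detect import Spot

__all__ = [
    "TrackingParams",
    "TrackFeatures",
    "Track",
    "KalmanState",
    "kalman_predict",
    "link_tracks",
    "compute_track_features",
    "classify_direction",
    "tracks_to_dataframe",
    "write_tracks_csv",
    "TRACK_CSV_COLUMNS",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"

_INFEASIBLE = 1e18


@dataclass(frozen=True)
class TrackingParams:
    """Linking parameters (defaults: 2 um search radius, 2-frame gap
    closing, 3 s minimum track duration)."""

    initial_search_radius_um: float = 2.0
    max_frame_gap: int = 2
    min_duration_s: float = 3.0
    # Kalman noise settings; measurement noise is given in pixels and
    # converted with the movie calibration.
    measurement_noise_px: float = 0.5
    process_noise_um_per_frame: float = 0.2

    def __post_init__(self) -> None:
        if self.initial_search_radius_um <= 0:
            raise ValueError("initial_search_radius_um must be > 0")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")
        if self.min_duration_s < 0:
            raise ValueError("min_duration_s must be >= 0")

    def min_frame_count(self, calibration: Calibration) -> int:
        """Minimum inclusive frame span implied by the duration filter
        (10 frames at the defaults)."""
        return math.ceil(self.min_duration_s * calibration.frames_per_second - 1e-9)


@dataclass(frozen=True)
class TrackFeatures:
    """Kinematic summary of one track (the nine dynamic parameters feed
    the phenotypic signature; angle/direction feed parameter #9)."""

    duration_s: float
    displacement_um: float
    length_um: float
    mean_speed_um_s: float
    max_speed_um_s: float
    min_speed_um_s: float
    median_speed_um_s: float
    sd_speed_um_s: float
    angle_rad: float
    direction: str


@dataclass
class Track:
    id: int
    spots: list[Spot]
    features: TrackFeatures | None = None

    @property
    def first_frame(self) -> int:
        return self.spots[0].frame

    @property
    def last_frame(self) -> int:
        return self.spots[-1].frame

    @property
    def frame_span(self) -> int:
        """Inclusive frame count from first to last spot."""
        return self.last_frame - self.first_frame + 1

    def __len__(self) -> int:
        return len(self.spots)


class KalmanState:
    """Constant-velocity Kalman filter over (x, y, vx, vy).

    Positions in um, velocities in um/frame; time is measured in frames
    so gap-closed links predict across the full gap span. A track with a
    single observation predicts its own position (zero prior velocity
    with large variance, so the second observation sets the velocity).
    """

    def __init__(
        self,
        x_um: float,
        y_um: float,
        meas_sigma_um: float,
        process_sigma_um: float,
        init_vel_sigma_um: float,
    ) -> None:
        self.state = np.array([x_um, y_um, 0.0, 0.0])
        self.P = np.diag(
            [meas_sigma_um**2, meas_sigma_um**2, init_vel_sigma_um**2, init_vel_sigma_um**2]
        )
        self.R = np.eye(2) * meas_sigma_um**2
        self._q = process_sigma_um**2

    def predict_position(self, dt_frames: float) -> np.ndarray:
        x, y, vx, vy = self.state
        return np.array([x + vx * dt_frames, y + vy * dt_frames])

    def advance(self, dt_frames: float, z_um: np.ndarray) -> None:
        """Predict over dt frames, then update with the measurement."""
        F = np.eye(4)
        F[0, 2] = F[1, 3] = dt_frames
        # Piecewise-constant white acceleration process noise.
        dt2, dt3, dt4 = dt_frames**2, dt_frames**3, dt_frames**4
        Q = self._q * np.array(
            [
                [dt4 / 4, 0, dt3 / 2, 0],
                [0, dt4 / 4, 0, dt3 / 2],
                [dt3 / 2, 0, dt2, 0],
                [0, dt3 / 2, 0, dt2],
            ]
        )
        self.state = F @ self.state
        self.P = F @ self.P @ F.T + Q
        H = np.zeros((2, 4))
        H[0, 0] = H[1, 1] = 1.0
        S = H @ self.P @ H.T + self.R
        K = self.P @ H.T @ np.linalg.inv(S)
        self.state = self.state + K @ (z_um - H @ self.state)
        self.P = (np.eye(4) - K @ H) @ self.P


def kalman_predict(track_state: KalmanState, dt_frames: float) -> np.ndarray:
    """Predicted (x, y) position dt frames ahead of the current state."""
    return track_state.predict_position(dt_frames)


class _LiveTrack:
    __slots__ = ("spots", "kalman", "created")

    def __init__(self, spot: Spot, kalman: KalmanState, created: int) -> None:
        self.spots = [spot]
        self.kalman = kalman
        self.created = created

    @property
    def last_frame(self) -> int:
        return self.spots[-1].frame


def link_tracks(
    spots_by_frame: list[list[Spot]],
    params: TrackingParams,
    calibration: Calibration,
) -> list[Track]:
    """Link per-frame detections into tracks and compute their features.

    Deterministic for fixed input: the assignment problem is solved
    exactly (Jonker-Volgenant) and new tracks are created in spot order.
    Returns only tracks passing the duration filter, with features
    attached; single-spot survivors cannot occur at any positive
    duration threshold spanning >= 2 frames.
    """
    meas_sigma_um = params.measurement_noise_px * calibration.pixel_size_um
    radius = params.initial_search_radius_um
    radius_sq = radius * radius

    live: list[_LiveTrack] = []
    finished: list[_LiveTrack] = []
    n_frames = len(spots_by_frame)
    serial = 0

    for f in range(n_frames):
        # Retire tracks that can no longer be resumed by gap closing.
        still_live = []
        for tr in live:
            if f - tr.last_frame > params.max_frame_gap + 1:
                finished.append(tr)
            else:
                still_live.append(tr)
        live = still_live

        spots = spots_by_frame[f]
        if live and spots:
            preds = np.array([tr.kalman.predict_position(f - tr.last_frame) for tr in live])
            pos = np.array([[s.x_um, s.y_um] for s in spots])
            d2 = ((preds[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= radius_sq, d2, _INFEASIBLE)
            rows, cols = linear_sum_assignment(cost)
            assigned_spots = set()
            for i, j in zip(rows, cols):
                if cost[i, j] >= _INFEASIBLE:
                    continue
                tr = live[i]
                tr.kalman.advance(f - tr.last_frame, pos[j])
                tr.spots.append(spots[j])
                assigned_spots.add(j)
        else:
            assigned_spots = set()

        for j, spot in enumerate(spots):
            if j in assigned_spots:
                continue
            kalman = KalmanState(
                spot.x_um,
                spot.y_um,
                meas_sigma_um=meas_sigma_um,
                process_sigma_um=params.process_noise_um_per_frame,
                init_vel_sigma_um=radius,
            )
            live.append(_LiveTrack(spot, kalman, created=serial))
            serial += 1

    finished.extend(live)
    finished.sort(key=lambda tr: (tr.spots[0].frame, tr.created))

    min_frames = params.min_frame_count(calibration)
    tracks: list[Track] = []
    for tr in finished:
        span = tr.spots[-1].frame - tr.spots[0].frame + 1
        if span < min_frames or len(tr.spots) < 2:
            continue
        track = Track(id=len(tracks), spots=tr.spots)
        track.features = compute_track_features(track, calibration)
        tracks.append(track)
    return tracks


def classify_direction(angle_rad: float) -> str:
    """Direction class from the net track angle.

    Angle 0 points rightward to the proximal site (retrograde), pi
    leftward to the distal site (anterograde); the closed interval
    [-pi/2, pi/2] is retrograde, everything else anterograde.
    """
    return RETROGRADE if -math.pi / 2 <= angle_rad <= math.pi / 2 else ANTEROGRADE


def compute_track_features(track: Track, calibration: Calibration) -> TrackFeatures:
    """Kinematic features of one track.

    Link speeds are distance / (frame gap * frame interval), so a
    gap-closed link contributes a single time-normalized speed. The
    speed SD uses the N-1 denominator over link speeds (0 when there is
    only one link). The angle is atan2 of the net displacement with the
    image y-axis negated, so 0 = rightward in standard math orientation.
    """
    if len(track.spots) < 2:
        raise OhpError(f"track {track.id} has {len(track.spots)} spot(s); need >= 2")
    dt_s = calibration.frame_interval_s
    pts = np.array([[s.x_um, s.y_um] for s in track.spots])
    frames = np.array([s.frame for s in track.spots])
    if not np.all(np.diff(frames) > 0):
        raise OhpError("track frames must be strictly increasing")
    seg = np.diff(pts, axis=0)
    dists = np.hypot(seg[:, 0], seg[:, 1])
    gaps_s = np.diff(frames) * dt_s
    speeds = dists / gaps_s
    dx = pts[-1, 0] - pts[0, 0]
    dy = pts[-1, 1] - pts[0, 1]
    # avoid -0.0 flipping atan2 from +pi to -pi; range must be (-pi, pi]
    angle = math.atan2(0.0 if dy == 0 else -dy, dx)
    return TrackFeatures(
        duration_s=(frames[-1] - frames[0] + 1) * dt_s,
        displacement_um=float(np.hypot(dx, dy)),
        length_um=float(dists.sum()),
        mean_speed_um_s=float(speeds.mean()),
        max_speed_um_s=float(speeds.max()),
        min_speed_um_s=float(speeds.min()),
        median_speed_um_s=float(np.median(speeds)),
        sd_speed_um_s=float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
        angle_rad=angle,
        direction=classify_direction(angle),
    )


TRACK_CSV_COLUMNS = [
    "Filename",
    "TrackID",
    "duration_s",
    "displacement_um",
    "length_um",
    "mean_speed_um_s",
    "max_speed_um_s",
    "min_speed_um_s",
    "median_speed_um_s",
    "sd_speed_um_s",
    "angle_rad",
    "direction",
]


def tracks_to_dataframe(tracks: list[Track], filename: str) -> pd.DataFrame:
    """One row per track, metadata columns left, features right."""
    rows = []
    for tr in tracks:
        ft = tr.features
        rows.append(
            {
                "Filename": filename,
                "TrackID": tr.id,
                "duration_s": ft.duration_s,
                "displacement_um": ft.displacement_um,
                "length_um": ft.length_um,
                "mean_speed_um_s": ft.mean_speed_um_s,
                "max_speed_um_s": ft.max_speed_um_s,
                "min_speed_um_s": ft.min_speed_um_s,
                "median_speed_um_s": ft.median_speed_um_s,
                "sd_speed_um_s": ft.sd_speed_um_s,
                "angle_rad": ft.angle_rad,
                "direction": ft.direction,
            }
        )
    return pd.DataFrame(rows, columns=TRACK_CSV_COLUMNS)


def write_tracks_csv(tracks: list[Track], filename: str, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks_to_dataframe(tracks, filename).to_csv(path, index=False, float_format="%.6g")
    return path
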