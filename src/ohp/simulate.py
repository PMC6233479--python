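"""Synthetic axonal-trafficking movie generator with ground truth.

Emulates the nominal acquisition (single-channel 16-bit stacks of
organelles moving along the axon axis) so that every downstream stage —
detection, tracking, morphology, mining, signatures, clustering — can be
validated against known truth without any microscope data.

Motion model: each organelle is stationary or moves at a constant
per-organelle speed along +-x, with optional per-frame pauses and no
reversals. Anterograde organelles move LEFT (negative x, toward the
distal site), retrograde organelles RIGHT (toward the proximal site),
matching the fixed distal-left / proximal-right storage orientation.
In vivo only a minority (~10-20%) of axonal mitochondria move
processively, hence the default stationary fraction of 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ohp.core import (
    Calibration,
    CalibratedMovie,
    ConditionKey,
    DEFAULT_CALIBRATION,
    OhpError,
    write_movie,
)

__all__ = [
    "MotilityModel",
    "AppearanceModel",
    "GroundTruthOrganelle",
    "GroundTruth",
    "simulate_movie",
    "render_shape_frame",
    "write_simulated_tree",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

STATIONARY = "stationary"
ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


@dataclass(frozen=True)
class MotilityModel:
    """Population-level motility settings for one simulated movie.

    Speeds are drawn once per moving organelle from a normal
    distribution truncated at zero; anterograde means leftward
    (negative x velocity). ``jitter_sd_um`` is positional noise applied
    to stationary organelles only, so moving organelles obey the
    linear-motion assumption of the tracker exactly.
    """

    n_organelles: int = 20
    stationary_fraction: float = 0.8
    anterograde_fraction_of_moving: float = 0.5
    speed_mean_um_s: float = 0.8
    speed_sd_um_s: float = 0.2
    jitter_sd_um: float = 0.02
    pause_probability: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "stationary_fraction",
            "anterograde_fraction_of_moving",
            "pause_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        if self.speed_mean_um_s < 0:
            raise ValueError("speed_mean_um_s must be >= 0")


@dataclass(frozen=True)
class AppearanceModel:
    """Rendering settings: organelle kernel shape and camera noise.

    ``diameter_um`` is the full-width-half-maximum of the rendered
    Gaussian kernel (default 1.6 um, the estimated organelle diameter
    used by the detector). Elliptical organelles stretch the FWHM along
    the major axis by ``ellipse_aspect``.
    """

    shape: str = "spot"  # {"spot", "ellipse"}
    diameter_um: float = 1.6
    ellipse_aspect: float = 1.0
    peak_intensity: float = 4000.0
    background_level: float = 400.0
    noise_model: str = "gaussian"  # {"gaussian", "poisson"}
    noise_scale: float = 40.0

    def __post_init__(self) -> None:
        if self.shape not in ("spot", "ellipse"):
            raise ValueError(f"shape must be 'spot' or 'ellipse', got {self.shape!r}")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")
        if self.ellipse_aspect < 1:
            raise ValueError("ellipse_aspect must be >= 1")
        if self.peak_intensity <= self.background_level:
            raise ValueError("peak_intensity must exceed background_level")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruthOrganelle:
    id: int
    direction: str  # stationary | anterograde | retrograde
    speed_um_s: float  # 0 for stationary
    positions_um: np.ndarray  # (T, 2) array of (x, y); NaN once exited
    diameter_um: float
    aspect: float
    orientation_rad: float = 0.0

    @property
    def exited(self) -> bool:
        return bool(np.isnan(self.positions_um).any())

    def net_x_displacement_um(self) -> float:
        valid = ~np.isnan(self.positions_um[:, 0])
        xs = self.positions_um[valid, 0]
        return float(xs[-1] - xs[0]) if xs.size >= 2 else 0.0


@dataclass
class GroundTruth:
    """Known per-organelle trajectories and shapes for one movie."""

    organelles: list[GroundTruthOrganelle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.organelles)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for org in self.organelles:
            for frame, (x, y) in enumerate(org.positions_um):
                if np.isnan(x):
                    continue
                rows.append(
                    {
                        "id": org.id,
                        "frame": frame,
                        "x_um": x,
                        "y_um": y,
                        "direction": org.direction,
                        "diameter_um": org.diameter_um,
                        "aspect": org.aspect,
                    }
                )
        columns = ["id", "frame", "x_um", "y_um", "direction", "diameter_um", "aspect"]
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path


def _gaussian_patch(
    image: np.ndarray,
    cx_px: float,
    cy_px: float,
    sigma_x_px: float,
    sigma_y_px: float,
    theta: float,
    amplitude: float,
) -> None:
    """Add an (optionally rotated) anisotropic Gaussian kernel in place.

    Only a window of +-4 sigma around the centre is evaluated; kernels
    whose window misses the image entirely are skipped.
    """
    H, W = image.shape
    reach = 4.0 * max(sigma_x_px, sigma_y_px)
    r0 = max(int(math.floor(cy_px - reach)), 0)
    r1 = min(int(math.ceil(cy_px + reach)) + 1, H)
    c0 = max(int(math.floor(cx_px - reach)), 0)
    c1 = min(int(math.ceil(cx_px + reach)) + 1, W)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None] + 0.5
    cols = np.arange(c0, c1)[None, :] + 0.5
    dx = cols - cx_px
    dy = rows - cy_px
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -0.5 * ((u / sigma_x_px) ** 2 + (v / sigma_y_px) ** 2)
    )


def render_shape_frame(
    shapes: list[tuple[tuple[float, float], float, float, float]],
    appearance: AppearanceModel,
    geometry: tuple[int, int],
    calibration: Calibration = DEFAULT_CALIBRATION,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame of Gaussian-kernel organelles.

    Parameters
    ----------
    shapes : list of ((x_um, y_um), diameter_um, aspect, orientation_rad)
        Each shape is a filled 2-D Gaussian whose FWHM equals
        ``diameter_um`` (minor axis; the major axis FWHM is
        ``diameter_um * aspect``).
    geometry : (H, W) in pixels.
    rng : optional generator; when given, noise per ``appearance`` is
        added. Without it the frame is noiseless (useful for oracles).

    Returns a uint16 image: background + kernels + noise, clipped to
    the 16-bit range.
    """
    H, W = geometry
    if H <= 0 or W <= 0:
        raise OhpError(f"geometry must be positive, got {(H, W)}")
    px = calibration.pixel_size_um
    image = np.full((H, W), float(appearance.background_level))
    amplitude = appearance.peak_intensity - appearance.background_level
    for (x_um, y_um), diameter_um, aspect, theta in shapes:
        if aspect < 1:
            raise OhpError(f"shape aspect must be >= 1, got {aspect}")
        sigma_minor = diameter_um * _FWHM_TO_SIGMA / px
        sigma_major = sigma_minor * aspect
        _gaussian_patch(
            image, x_um / px, y_um / px, sigma_major, sigma_minor, theta, amplitude
        )
    if rng is not None:
        if appearance.noise_model == "gaussian":
            image = image + rng.normal(0.0, appearance.noise_scale, size=image.shape)
        else:
            image = rng.poisson(np.clip(image, 0, None)).astype(float)
    return np.clip(np.round(image), 0, 65535).astype(np.uint16)


def _assign_lanes(
    n: int, height_um: float, margin_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Spread organelles over distinct y lanes so tracks do not cross."""
    usable = max(height_um - 2 * margin_um, 1e-6)
    if n == 1:
        return np.array([height_um / 2.0])
    lanes = margin_um + usable * (np.arange(n) + 0.5) / n
    rng.shuffle(lanes)
    return lanes


def simulate_movie(
    motility: MotilityModel,
    appearance: AppearanceModel,
    geometry: tuple[int, int, int],
    calibration: Calibration = DEFAULT_CALIBRATION,
    seed: int = 0,
    channel: str = "Mitotracker",
) -> tuple[CalibratedMovie, GroundTruth]:
    """Simulate one calibrated movie plus its ground truth.

    ``geometry`` is (T, H, W). Deterministic given the seed: identical
    inputs produce bit-identical frames and ground truth. Moving
    organelles travel along +-x at a per-organelle speed drawn from
    N(speed_mean, speed_sd) truncated at zero; organelles leaving the
    field are truncated in the ground truth (positions become NaN), not
    wrapped.
    """
    T, H, W = geometry
    if T <= 0 or H <= 0 or W <= 0:
        raise OhpError(f"geometry must be positive, got {geometry}")
    rng = np.random.default_rng(seed)
    px = calibration.pixel_size_um
    dt = calibration.frame_interval_s
    width_um, height_um = W * px, H * px
    margin_um = appearance.diameter_um

    n = motility.n_organelles
    organelles: list[GroundTruthOrganelle] = []
    lanes = _assign_lanes(n, height_um, margin_um, rng) if n else np.empty(0)
    for i in range(n):
        stationary = rng.random() < motility.stationary_fraction
        if stationary:
            direction, speed, vx = STATIONARY, 0.0, 0.0
        else:
            antero = rng.random() < motility.anterograde_fraction_of_moving
            direction = ANTEROGRADE if antero else RETROGRADE
            speed = max(rng.normal(motility.speed_mean_um_s, motility.speed_sd_um_s), 0.0)
            vx = -speed if antero else speed

        y0 = lanes[i]
        # Start moving organelles deep enough into the field that most of
        # the trajectory is observed before exit.
        if direction == ANTEROGRADE:
            x0 = rng.uniform(width_um * 0.5, width_um - margin_um)
        elif direction == RETROGRADE:
            x0 = rng.uniform(margin_um, width_um * 0.5)
        else:
            x0 = rng.uniform(margin_um, width_um - margin_um)

        positions = np.empty((T, 2))
        x = x0
        exited = False
        for t in range(T):
            if exited:
                positions[t] = (np.nan, np.nan)
                continue
            if direction == STATIONARY:
                jx = rng.normal(0.0, motility.jitter_sd_um)
                jy = rng.normal(0.0, motility.jitter_sd_um)
                positions[t] = (x0 + jx, y0 + jy)
            else:
                positions[t] = (x, y0)
                paused = rng.random() < motility.pause_probability
                if not paused:
                    x += vx * dt
                if not (0.0 <= x <= width_um):
                    exited = True
        organelles.append(
            GroundTruthOrganelle(
                id=i,
                direction=direction,
                speed_um_s=speed,
                positions_um=positions,
                diameter_um=appearance.diameter_um,
                aspect=appearance.ellipse_aspect if appearance.shape == "ellipse" else 1.0,
            )
        )

    frames = np.empty((T, H, W), dtype=np.uint16)
    for t in range(T):
        shapes = []
        for org in organelles:
            x, y = org.positions_um[t]
            if np.isnan(x):
                continue
            shapes.append(((x, y), org.diameter_um, org.aspect, org.orientation_rad))
        frames[t] = render_shape_frame(shapes, appearance, (H, W), calibration, rng=rng)

    movie = CalibratedMovie(
        frames=frames,
        calibration=calibration,
        channel=channel,
        source_path=f"simulated(seed={seed})",
    )
    return movie, GroundTruth(organelles=organelles)


def write_simulated_tree(
    root: str | Path,
    condition: ConditionKey,
    movie_name: str,
    movie: CalibratedMovie,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a simulated movie (and optional ground truth CSV) into the
    standard seven-level folder layout under ``root``."""
    root = Path(root)
    folder = root.joinpath(*(getattr(condition, f) for f in condition.as_dict()))
    folder.mkdir(parents=True, exist_ok=True)
    tiff_path = folder / movie_name
    write_movie(movie, tiff_path)
    if ground_truth is not None:
        ground_truth.to_csv(folder / (tiff_path.stem + "_groundtruth.csv"))
    return tiff_path
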