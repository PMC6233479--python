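"""Shared domain types: spatial/temporal calibration, calibrated movies,
and experimental-condition metadata parsed from the folder tree.

Coordinate convention
---------------------
Pixels are addressed as (row, col) with the origin at the top-left of the
image. Continuous positions are in micrometres, with x = col axis
increasing rightward and y = row axis increasing downward; the position
of pixel index ``i`` is ``(i + 0.5) * pixel_size_um`` (pixel centres).
Movies are stored so that the distal axon site is on the LEFT and the
proximal (soma) site on the RIGHT; this fixed orientation is what makes
the track-angle direction rule meaningful.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "OhpError",
    "MetadataError",
    "MovieFormatError",
    "Calibration",
    "DEFAULT_CALIBRATION",
    "CalibratedMovie",
    "ConditionKey",
    "DEFAULT_TEMPLATE",
    "MARKERS",
    "READOUT_POSITIONS",
    "parse_condition_from_path",
    "load_movie",
    "write_movie",
]


class OhpError(Exception):
    """Base class for errors raised by this package."""


class MetadataError(OhpError):
    """Folder-tree metadata could not be parsed into a condition key."""


class MovieFormatError(OhpError):
    """A movie file does not meet the grayscale multi-page TIFF contract."""


MARKERS = ("Mitotracker", "Lysotracker")
READOUT_POSITIONS = ("Distal", "Proximal")

#: Folder levels encoding the experimental condition, outermost first.
#: The movie filename itself is not part of the template.
DEFAULT_TEMPLATE = (
    "project",
    "experiment",
    "marker",
    "readout_position",
    "treatment",
    "disease",
    "line",
)


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of an acquisition.

    Parameters
    ----------
    pixel_size_um : float
        Micrometres per pixel (nominal acquisition: 0.22955 um/px at
        100x magnification).
    frame_interval_s : float
        Seconds per frame (nominal acquisition: 3.3 frames per second,
        i.e. 1/3.3 s).
    """

    pixel_size_um: float = 0.22955
    frame_interval_s: float = 1.0 / 3.3

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )

    @property
    def frames_per_second(self) -> float:
        return 1.0 / self.frame_interval_s

    @classmethod
    def from_fps(cls, pixel_size_um: float, frames_per_second: float) -> "Calibration":
        return cls(pixel_size_um=pixel_size_um, frame_interval_s=1.0 / frames_per_second)


DEFAULT_CALIBRATION = Calibration()


@dataclass
class CalibratedMovie:
    """A single-channel time-lapse stack with physical calibration.

    ``frames`` is a (T, H, W) non-negative integer array in the 16-bit
    range; the nominal acquisition is 400 frames of 512 x 512 px, giving
    a field of view of 512 * 0.22955 = 117.53 um.
    """

    frames: np.ndarray
    calibration: Calibration
    channel: str
    source_path: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise MovieFormatError(
                f"frames must be a T x H x W array, got shape {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise MovieFormatError("movie must contain at least one frame")
        if not np.issubdtype(frames.dtype, np.integer):
            raise MovieFormatError(f"frames must be integer-typed, got {frames.dtype}")
        if frames.min() < 0 or frames.max() > 65535:
            raise MovieFormatError("intensities must lie in the 16-bit range [0, 65535]")
        self.frames = frames.astype(np.uint16, copy=False)
        if self.channel not in MARKERS:
            raise ValueError(f"channel must be one of {MARKERS}, got {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def width_um(self) -> float:
        return self.width * self.calibration.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height * self.calibration.pixel_size_um

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.calibration.frame_interval_s


@dataclass(frozen=True)
class ConditionKey:
    """Experimental metadata of one movie, one field per folder level.

    Hashable so it can serve directly as the pooling key when batching
    per-movie results into per-condition statistics.
    """

    project: str
    experiment: str
    marker: str
    readout_position: str
    treatment: str
    disease: str
    line: str

    def __post_init__(self) -> None:
        for name in DEFAULT_TEMPLATE:
            if not getattr(self, name):
                raise MetadataError(f"condition field {name!r} must be non-empty")
        if self.marker not in MARKERS:
            raise MetadataError(
                f"marker {self.marker!r} not recognized; allowed: {list(MARKERS)}"
            )
        if self.readout_position not in READOUT_POSITIONS:
            raise MetadataError(
                f"readout_position {self.readout_position!r} not recognized; "
                f"allowed: {list(READOUT_POSITIONS)}"
            )

    def as_dict(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in DEFAULT_TEMPLATE}


def _split_path_levels(path: str) -> list[str]:
    # Accept both POSIX and Windows separator styles and trailing separators.
    normalized = re.sub(r"[\\/]+", "/", str(path)).rstrip("/")
    parts = [p for p in normalized.split("/") if p and p != "."]
    # Drop drive specifiers like "X:" (the layout in the wild is rooted there).
    if parts and re.fullmatch(r"[A-Za-z]:", parts[0]):
        parts = parts[1:]
    return parts


def parse_condition_from_path(
    path: str | Path,
    template: tuple[str, ...] = DEFAULT_TEMPLATE,
) -> ConditionKey:
    """Extract the experimental condition from a movie/CSV file path.

    The last ``len(template)`` directory levels above the filename are
    mapped onto the template fields in order, e.g. for the default
    seven-level layout ``Project/Experiment/Marker/Readout position/
    Treatment/Disease/Line/movie.tif``.

    Pure function of its inputs; invariant to separator style and
    trailing separators.
    """
    unknown = set(template) - set(DEFAULT_TEMPLATE)
    if unknown:
        raise MetadataError(f"unknown template levels: {sorted(unknown)}")
    parts = _split_path_levels(path)
    levels = parts[:-1]  # exclude the movie filename
    if len(levels) < len(template):
        missing = template[: len(template) - len(levels)]
        raise MetadataError(
            f"path {str(path)!r} has {len(levels)} directory levels but the "
            f"template needs {len(template)}; missing level(s): {list(missing)}"
        )
    values = dict(zip(template, levels[-len(template):]))
    return ConditionKey(**values)


def load_movie(
    path: str | Path,
    calibration: Calibration = DEFAULT_CALIBRATION,
    channel: str = "Mitotracker",
) -> CalibratedMovie:
    """Read a grayscale multi-page TIFF stack as a calibrated movie.

    Frames are kept in stored order and intensities preserved exactly
    (uint8 input is promoted to uint16 without rescaling). Calibration
    is supplied by the caller, never inferred from TIFF tags; if
    resolution tags are present and disagree, a warning is emitted.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise MovieFormatError(f"{path}: TIFF contains zero pages")
        first = tif.pages[0]
        if (first.samplesperpixel or 1) != 1:
            raise MovieFormatError(
                f"{path}: multi-sample (RGB) TIFF pages are not supported; "
                "expected single-channel grayscale"
            )
        _warn_on_conflicting_tags(path, first, calibration)
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[np.newaxis, ...]
    if frames.ndim != 3:
        raise MovieFormatError(
            f"{path}: expected a stack of 2-D grayscale pages, got shape {frames.shape}"
        )
    return CalibratedMovie(
        frames=frames.astype(np.uint16),
        calibration=calibration,
        channel=channel,
        source_path=str(path),
    )


def _warn_on_conflicting_tags(path: Path, page, calibration: Calibration) -> None:
    tag = page.tags.get("XResolution")
    if tag is None:
        return
    num, den = tag.value
    if num == 0 or den == 0 or num == den:  # (1, 1) is the "no info" default
        return
    # TIFF XResolution is px per resolution unit; without a reliable unit
    # convention we only flag gross disagreement with the configured scale.
    tag_pixel_um = den / num * 1e4  # assume cm unit, the common microscopy export
    if not np.isclose(tag_pixel_um, calibration.pixel_size_um, rtol=0.05):
        warnings.warn(
            f"{path}: TIFF resolution tag implies {tag_pixel_um:.4g} um/px but "
            f"calibration says {calibration.pixel_size_um:.4g} um/px; "
            "using the configured calibration",
            stacklevel=3,
        )


def write_movie(movie: CalibratedMovie, path: str | Path) -> Path:
    """Write a calibrated movie as an uncompressed uint16 multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels_per_cm = 1e4 / movie.calibration.pixel_size_um
    tifffile.imwrite(
        path,
        movie.frames.astype(np.uint16),
        photometric="minisblack",
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path
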