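"""Pipeline configuration: one nested structure holding calibration,
folder template, and every stage's parameters, loadable from YAML and
overridable per field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from ohp.core import Calibration, DEFAULT_TEMPLATE, OhpError
from ohp.detect import DetectionParams
from ohp.mine import FilterParams
from ohp.track import TrackingParams

__all__ = ["MorphologyParams", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class MorphologyParams:
    threshold_method: str = "isodata"
    min_area_px: int = 4


@dataclass(frozen=True)
class PipelineConfig:
    calibration: Calibration = field(default_factory=Calibration)
    template: tuple[str, ...] = DEFAULT_TEMPLATE
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    filter: FilterParams = field(default_factory=FilterParams)
    baseline: dict = field(default_factory=lambda: {"treatment": "Mock", "disease": "Ctrl"})
    significance_band: float = 5.0
    welch: bool = False
    cluster_subset: str = "full"
    seed: int = 0
    flip_x: bool = False  # set for acquisitions mirrored left-right

    def override(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


_SECTIONS = {
    "calibration": Calibration,
    "detection": DetectionParams,
    "tracking": TrackingParams,
    "morphology": MorphologyParams,
    "filter": FilterParams,
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file (missing file
    fields keep their defaults); None returns all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise OhpError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise OhpError(f"config file {path} must contain a mapping")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw.pop(name)
            valid = {f.name for f in fields(cls)}
            unknown = set(section) - valid
            if unknown:
                raise OhpError(f"config section {name!r}: unknown keys {sorted(unknown)}")
            kwargs[name] = cls(**section)
    if "template" in raw:
        kwargs["template"] = tuple(raw.pop("template"))
    for key in ("baseline", "significance_band", "welch", "cluster_subset", "seed", "flip_x"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise OhpError(f"unknown config keys: {sorted(raw)}")
    return PipelineConfig(**kwargs)
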