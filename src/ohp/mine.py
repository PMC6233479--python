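"""Result mining: recursive discovery of per-movie CSVs in the folder
tree, metadata joining from the path levels, and the displacement row
filter that removes non-processive jitter tracks.

Each movie leaves two CSVs beside it — ``<stem>_tracks.csv`` from the
tracking stage and ``<stem>_morphology.csv`` from the morphology stage.
Mining collects one kind at a time into a long-format table whose left
columns are the seven condition fields plus Filename, and whose right
columns are the per-record features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ohp.core import (
    DEFAULT_TEMPLATE,
    MetadataError,
    OhpError,
    parse_condition_from_path,
)

__all__ = [
    "FilterParams",
    "TRACKS_SUFFIX",
    "MORPHOLOGY_SUFFIX",
    "collect_results",
    "filter_displacement",
    "write_result_table",
]

logger = logging.getLogger(__name__)

TRACKS_SUFFIX = "_tracks.csv"
MORPHOLOGY_SUFFIX = "_morphology.csv"
_KIND_SUFFIX = {"tracks": TRACKS_SUFFIX, "morphology": MORPHOLOGY_SUFFIX}
_KIND_ID = {"tracks": "TrackID", "morphology": "particle_id"}


@dataclass(frozen=True)
class FilterParams:
    """Row-filter settings; tracks displaced less than 1.2 um are
    treated as non-processive jitter and excluded."""

    min_displacement_um: float = 1.2

    def __post_init__(self) -> None:
        if self.min_displacement_um < 0:
            raise ValueError("min_displacement_um must be >= 0")


def collect_results(
    root: str | Path,
    kind: str,
    template: tuple[str, ...] = DEFAULT_TEMPLATE,
) -> pd.DataFrame:
    """Collect all per-movie CSVs of one kind under ``root``.

    Every matching file is parsed and joined with the condition derived
    from its path; files too shallow for the template are skipped with
    a warning. Row order is deterministic: lexicographic by relative
    path, then record id.
    """
    if kind not in _KIND_SUFFIX:
        raise OhpError(f"kind must be one of {sorted(_KIND_SUFFIX)}, got {kind!r}")
    root = Path(root)
    if not root.exists():
        raise OhpError(f"result root {root} does not exist")
    suffix = _KIND_SUFFIX[kind]
    paths = sorted(p for p in root.rglob(f"*{suffix}") if p.is_file())
    frames: list[pd.DataFrame] = []
    for path in paths:
        try:
            condition = parse_condition_from_path(path, template)
        except MetadataError as exc:
            warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV: name the file
            raise OhpError(f"malformed CSV {path}: {exc}") from exc
        for name in reversed(template):
            df.insert(0, name, getattr(condition, name))
        frames.append(df.sort_values(_KIND_ID[kind], kind="stable"))
    if not frames:
        warnings.warn(f"no {kind} CSVs found under {root}", stacklevel=2)
        return pd.DataFrame(columns=list(template))
    table = pd.concat(frames, ignore_index=True)
    logger.info("collected %d %s rows from %d files", len(table), kind, len(frames))
    return table


def filter_displacement(table: pd.DataFrame, params: FilterParams = FilterParams()) -> pd.DataFrame:
    """Keep tracks with displacement >= min_displacement_um (idempotent).

    Applies to the tracks table only; morphology records are never
    displacement-filtered.
    """
    if "displacement_um" not in table.columns:
        raise OhpError("table has no displacement_um column; is this a tracks table?")
    out = table[table["displacement_um"] >= params.min_displacement_um]
    return out.reset_index(drop=True)


def write_result_table(table: pd.DataFrame, path: str | Path, xlsx: bool = False) -> Path:
    """Write the long-format result table (CSV; optionally an XLSX mirror)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6g")
    if xlsx:
        table.to_excel(path.with_suffix(".xlsx"), index=False)
    return path
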