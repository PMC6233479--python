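"""Assembly of 40-parameter phenotypic high-content signatures.

Per condition, each parameter's pooled mean is expressed as a Z-score
deviation from the proximal Mock-treated control baseline of the SAME
marker::

    Z = (mean_C - mean_ctrl) / (SD_C/sqrt(N_C) + SD_ctrl/sqrt(N_ctrl))

i.e. the mean difference divided by the sum of the two standard errors
(a Welch-style denominator sqrt(SD_C^2/N_C + SD_ctrl^2/N_ctrl) is
available behind ``welch=True`` for sensitivity analysis). |Z| >= 5 is
flagged as significant.

The signature concatenates four blocks of ten parameters in fixed
order — Mitotracker Distal (#1-10), Mitotracker Proximal (#11-20),
Lysotracker Distal (#21-30), Lysotracker Proximal (#31-40). Within a
block: eight per-track kinematic parameters, the per-movie ratio of
anterograde to retrograde track counts (#9), and one per-organelle
morphology parameter (#10): aspect ratio for mitochondria, outer Feret
diameter for the globular lysosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ohp.core import OhpError

__all__ = [
    "SignatureError",
    "ConditionStats",
    "SignatureEntry",
    "Signature",
    "BLOCKS",
    "DYNAMIC_PARAMETERS",
    "zscore",
    "antero_retro_ratio",
    "condition_stats",
    "assemble_signature",
    "write_zscores_csv",
    "plot_signature",
]


class SignatureError(OhpError):
    pass


#: (block label, marker, readout) in canonical #1-40 order.
BLOCKS = (
    ("Mito-Distal", "Mitotracker", "Distal"),
    ("Mito-Proximal", "Mitotracker", "Proximal"),
    ("Lyso-Distal", "Lysotracker", "Distal"),
    ("Lyso-Proximal", "Lysotracker", "Proximal"),
)

#: The eight per-track parameters, in order, as (display name, column).
DYNAMIC_PARAMETERS = (
    ("Track Duration", "duration_s"),
    ("Track Displacement", "displacement_um"),
    ("Track Mean Speed", "mean_speed_um_s"),
    ("Track Max Speed", "max_speed_um_s"),
    ("Track Min Speed", "min_speed_um_s"),
    ("Track Median Speed", "median_speed_um_s"),
    ("Track SD Speed", "sd_speed_um_s"),
    ("Track Length", "length_um"),
)

RATIO_PARAMETER = "Ratio Antero-/Retrograde Tracks"

#: Marker-specific morphology parameter (#10 of each block).
SHAPE_PARAMETER = {
    "Mitotracker": ("Mitochondrial Aspect Ratio", "aspect_ratio"),
    "Lysotracker": ("Lysosomal Feret Diameter", "feret_max_um"),
}

DEFAULT_SIGNIFICANCE_BAND = 5.0


@dataclass(frozen=True)
class ConditionStats:
    """Pooled sample statistics of one parameter at one condition."""

    parameter: str
    mean: float
    sd: float  # N-1 denominator
    n: int

    @classmethod
    def from_values(cls, parameter: str, values: np.ndarray) -> "ConditionStats":
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size < 1:
            raise SignatureError(f"no finite values for parameter {parameter!r}")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(parameter=parameter, mean=float(values.mean()), sd=sd, n=int(values.size))

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


def zscore(
    stats_c: ConditionStats, stats_ctrl: ConditionStats, welch: bool = False
) -> float:
    """Z-score of a condition against the baseline for one parameter.

    Antisymmetric under swapping condition and baseline. Equal means
    give exactly 0; unequal means with a zero denominator (both SDs
    zero) are an error.
    """
    if stats_c.parameter != stats_ctrl.parameter:
        raise SignatureError(
            f"parameter mismatch: {stats_c.parameter!r} vs {stats_ctrl.parameter!r}"
        )
    for s in (stats_c, stats_ctrl):
        if s.n < 2:
            raise SignatureError(
                f"parameter {s.parameter!r}: n = {s.n} < 2, cannot form a standard error"
            )
    diff = stats_c.mean - stats_ctrl.mean
    if diff == 0.0:
        return 0.0
    if welch:
        denom = math.sqrt(stats_c.sd**2 / stats_c.n + stats_ctrl.sd**2 / stats_ctrl.n)
    else:
        denom = stats_c.sem + stats_ctrl.sem
    if denom == 0.0:
        raise SignatureError(
            f"parameter {stats_c.parameter!r}: both SDs are zero with unequal means"
        )
    return diff / denom


def antero_retro_ratio(directions) -> float | None:
    """Per-movie ratio of anterograde to retrograde track counts.

    Returns None (movie excluded from pooling for this parameter) when
    there are no retrograde tracks to divide by.
    """
    directions = list(directions)
    n_antero = sum(d == "anterograde" for d in directions)
    n_retro = sum(d == "retrograde" for d in directions)
    if n_retro == 0:
        return None
    return n_antero / n_retro


@dataclass(frozen=True)
class SignatureEntry:
    index: int  # 1-40
    block: str
    parameter: str
    z: float
    n: int  # condition-pool sample size

    def significant(self, band: float = DEFAULT_SIGNIFICANCE_BAND) -> bool:
        return abs(self.z) >= band


@dataclass
class Signature:
    """Ordered 40-entry Z-score signature of one condition."""

    label: str
    entries: list[SignatureEntry]
    significance_band: float = DEFAULT_SIGNIFICANCE_BAND

    def __post_init__(self) -> None:
        if [e.index for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise SignatureError("signature entries must be consecutively indexed from 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def z_values(self) -> np.ndarray:
        return np.array([e.z for e in self.entries])

    @property
    def parameter_names(self) -> list[str]:
        return [f"{e.block}: {e.parameter}" for e in self.entries]

    def subset_indices(self, subset: str) -> np.ndarray:
        """Entry positions (0-based) for 'full', 'distal' or 'proximal'."""
        if subset == "full":
            return np.arange(len(self.entries))
        if subset not in ("distal", "proximal"):
            raise SignatureError(f"unknown subset {subset!r}")
        want = "Distal" if subset == "distal" else "Proximal"
        return np.array(
            [i for i, e in enumerate(self.entries) if e.block.endswith(want)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.entries],
                "block": [e.block for e in self.entries],
                "parameter": [e.parameter for e in self.entries],
                "z": [e.z for e in self.entries],
                "n": [e.n for e in self.entries],
                "significant": [e.significant(self.significance_band) for e in self.entries],
            }
        )


def _select(table: pd.DataFrame, marker: str, readout: str, selector: dict) -> pd.DataFrame:
    subset = table[(table["marker"] == marker) & (table["readout_position"] == readout)]
    for name, value in selector.items():
        if value is not None:
            subset = subset[subset[name] == value]
    return subset


def condition_stats(
    tracks: pd.DataFrame, morphology: pd.DataFrame, marker: str, readout: str, selector: dict
) -> dict[str, ConditionStats]:
    """Pooled statistics for the ten parameters of one block.

    Per-track parameters pool every filtered track; the ratio parameter
    pools one value per movie (movies without retrograde tracks are
    dropped with reduced n); the morphology parameter pools every
    segmented organelle.
    """
    tr = _select(tracks, marker, readout, selector)
    mo = _select(morphology, marker, readout, selector)
    if tr.empty or mo.empty:
        missing = "tracks" if tr.empty else "morphology"
        raise SignatureError(
            f"empty {missing} pool for marker={marker}, readout={readout}, "
            f"selector={selector}"
        )
    stats: dict[str, ConditionStats] = {}
    for name, column in DYNAMIC_PARAMETERS:
        stats[name] = ConditionStats.from_values(name, tr[column].to_numpy())
    ratios = [
        r
        for _, movie_rows in tr.groupby("Filename", sort=True)
        if (r := antero_retro_ratio(movie_rows["direction"])) is not None
    ]
    if not ratios:
        raise SignatureError(
            f"no movie with a defined antero/retrograde ratio for marker={marker}, "
            f"readout={readout}, selector={selector}"
        )
    stats[RATIO_PARAMETER] = ConditionStats.from_values(RATIO_PARAMETER, np.array(ratios))
    shape_name, shape_col = SHAPE_PARAMETER[marker]
    stats[shape_name] = ConditionStats.from_values(shape_name, mo[shape_col].to_numpy())
    return stats


def assemble_signature(
    tracks: pd.DataFrame,
    morphology: pd.DataFrame,
    condition: dict,
    baseline: dict,
    label: str | None = None,
    significance_band: float = DEFAULT_SIGNIFICANCE_BAND,
    welch: bool = False,
) -> Signature:
    """Assemble the ordered 40-parameter signature of one condition.

    ``condition`` and ``baseline`` are selectors over the non-marker,
    non-readout metadata fields (e.g. ``{"treatment": "Mock",
    "disease": "FUS"}``); fields omitted or None pool across their
    levels. The baseline is always evaluated at the Proximal readout of
    the block's own marker, whatever the block's readout.

    ``tracks`` must already be displacement-filtered.
    """
    entries: list[SignatureEntry] = []
    index = 1
    for block_label, marker, readout in BLOCKS:
        cond_stats = condition_stats(tracks, morphology, marker, readout, condition)
        base_stats = condition_stats(tracks, morphology, marker, "Proximal", baseline)
        for name in cond_stats:
            z = zscore(cond_stats[name], base_stats[name], welch=welch)
            entries.append(
                SignatureEntry(
                    index=index,
                    block=block_label,
                    parameter=name,
                    z=z,
                    n=cond_stats[name].n,
                )
            )
            index += 1
    if label is None:
        label = "/".join(str(v) for v in condition.values() if v is not None) or "all"
    return Signature(label=label, entries=entries, significance_band=significance_band)


def write_zscores_csv(signatures: list[Signature], path: str | Path) -> Path:
    """Write the Z-score table: one row per parameter index, one (z, n,
    significant) column set per condition."""
    if not signatures:
        raise SignatureError("no signatures to write")
    base = signatures[0].to_dataframe()[["index", "block", "parameter"]]
    for sig in signatures:
        df = sig.to_dataframe()
        if not df["parameter"].equals(base["parameter"]):
            raise SignatureError(f"signature {sig.label!r} has mismatched parameter order")
        base[f"z[{sig.label}]"] = df["z"]
        base[f"n[{sig.label}]"] = df["n"]
        base[f"significant[{sig.label}]"] = df["significant"]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base.to_csv(path, index=False, float_format="%.6g")
    return path


def plot_signature(signatures: list[Signature], path: str | Path) -> Path:
    """Z-score profile plot over parameter index with the +-band lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for sig in signatures:
        ax.plot(range(1, len(sig) + 1), sig.z_values, marker="o", ms=3, label=sig.label)
    band = signatures[0].significance_band
    for y in (band, -band):
        ax.axhline(y, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("parameter #")
    ax.set_ylabel("Z-score vs proximal control baseline")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
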