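"""End-to-end orchestration: per-movie analysis, folder-tree runs, and
the standard synthetic benchmark experiment.

Stages mirror the acquisition-to-signature workflow: simulate (or load)
movies, detect + track per movie, measure first-frame morphology per
movie, mine the per-movie CSVs into condition-annotated tables, apply
the displacement filter, assemble Z-score signatures, and cluster them.
Each stage is a pure function of (inputs, config, seed), so reruns with
identical settings produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ohp.cluster import Dendrogram, average_linkage, signature_distance_matrix, write_merge_table
from ohp.config import PipelineConfig
from ohp.core import CalibratedMovie, ConditionKey, load_movie, parse_condition_from_path
from ohp.detect import detect_spots
from ohp.mine import collect_results, filter_displacement, write_result_table
from ohp.morphology import measure_particles, threshold_first_frame, write_morphology_csv
from ohp.signature import Signature, assemble_signature, write_zscores_csv
from ohp.simulate import (
    AppearanceModel,
    GroundTruth,
    MotilityModel,
    simulate_movie,
    write_simulated_tree,
)
from ohp.track import Track, link_tracks, write_tracks_csv

__all__ = [
    "analyze_movie",
    "analyze_tree",
    "mine_tree",
    "SyntheticCondition",
    "simulate_experiment",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)


def analyze_movie(
    movie: CalibratedMovie, config: PipelineConfig, out_dir: Path | None = None,
    stem: str | None = None,
) -> tuple[list[Track], list]:
    """Track and measure one movie; optionally write its two CSVs."""
    if movie.n_frames < 2:
        raise ValueError("tracking needs a movie with at least 2 frames")
    if config.flip_x:
        movie = replace(movie, frames=movie.frames[:, :, ::-1].copy())
    spots = detect_spots(movie, config.detection)
    tracks = link_tracks(spots, config.tracking, movie.calibration)
    mask = threshold_first_frame(movie, config.morphology.threshold_method)
    shapes = measure_particles(
        mask, movie.frames[0], movie.calibration, config.morphology.min_area_px
    )
    n_spots = sum(len(s) for s in spots)
    logger.info(
        "%s: %d spots, %d tracks after duration filter, %d particles",
        stem or movie.source_path, n_spots, len(tracks), len(shapes),
    )
    if out_dir is not None and stem is not None:
        write_tracks_csv(tracks, stem, Path(out_dir) / f"{stem}_tracks.csv")
        write_morphology_csv(shapes, stem, Path(out_dir) / f"{stem}_morphology.csv")
    return tracks, shapes


def analyze_tree(root: str | Path, config: PipelineConfig) -> int:
    """Analyze every TIFF movie under ``root``, writing the per-movie
    tracks and morphology CSVs beside each movie. Returns the movie count."""
    root = Path(root)
    movies = sorted(p for p in root.rglob("*.tif")) + sorted(root.rglob("*.tiff"))
    count = 0
    for path in movies:
        condition = parse_condition_from_path(path, config.template)
        movie = load_movie(path, config.calibration, channel=condition.marker)
        analyze_movie(movie, config, out_dir=path.parent, stem=path.stem)
        count += 1
    logger.info("analyzed %d movies under %s", count, root)
    return count


def mine_tree(
    root: str | Path, config: PipelineConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collect and filter the per-movie CSVs into the two long-format
    result tables (tracks displacement-filtered, morphology untouched)."""
    tracks = collect_results(root, "tracks", config.template)
    if not tracks.empty:
        tracks = filter_displacement(tracks, config.filter)
    morphology = collect_results(root, "morphology", config.template)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_result_table(tracks, out_dir / "dynamic_tracking_parameters.csv")
        write_result_table(morphology, out_dir / "static_morphology_parameters.csv")
    return tracks, morphology


@dataclass(frozen=True)
class SyntheticCondition:
    """One simulated experimental condition.

    ``distal_speed_factor`` scales moving-organelle speed at the distal
    readout only (e.g. 0.5 models a distal trafficking slow-down while
    the proximal site stays normal); ``mito_aspect`` sets the rendered
    mitochondrial elongation.
    """

    treatment: str
    disease: str
    line: str = "Line1"
    distal_speed_factor: float = 1.0
    proximal_speed_factor: float = 1.0
    mito_aspect: float = 2.0


def simulate_experiment(
    root: str | Path,
    conditions: list[SyntheticCondition],
    config: PipelineConfig,
    motility: MotilityModel | None = None,
    appearance: AppearanceModel | None = None,
    geometry: tuple[int, int, int] = (60, 64, 128),
    movies_per_condition: int = 2,
    seed: int = 0,
    project: str = "SimProject",
    experiment: str = "Exp1",
) -> Path:
    """Simulate a full folder tree: every condition at both markers and
    both readout positions, with ground-truth CSVs beside the movies.

    Seeds for individual movies are derived deterministically from
    ``seed`` and the movie's position in the tree.
    """
    root = Path(root)
    motility = motility or MotilityModel()
    appearance = appearance or AppearanceModel()
    counter = 0
    for cond in conditions:
        for marker in ("Mitotracker", "Lysotracker"):
            if marker == "Mitotracker":
                app = replace(appearance, shape="ellipse", ellipse_aspect=cond.mito_aspect)
            else:
                app = replace(appearance, shape="spot", ellipse_aspect=1.0)
            for readout in ("Distal", "Proximal"):
                factor = (
                    cond.distal_speed_factor if readout == "Distal" else cond.proximal_speed_factor
                )
                mot = replace(
                    motility,
                    speed_mean_um_s=motility.speed_mean_um_s * factor,
                    speed_sd_um_s=motility.speed_sd_um_s * factor,
                )
                key = ConditionKey(
                    project=project,
                    experiment=experiment,
                    marker=marker,
                    readout_position=readout,
                    treatment=cond.treatment,
                    disease=cond.disease,
                    line=cond.line,
                )
                for m in range(movies_per_condition):
                    movie_seed = (seed * 100003 + counter) % (2**31 - 1)
                    counter += 1
                    movie, truth = simulate_movie(
                        mot, app, geometry, config.calibration, seed=movie_seed,
                        channel=marker,
                    )
                    write_simulated_tree(root, key, f"movie{m + 1}.tif", movie, truth)
    return root


def run_full_pipeline(
    root: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
    conditions: list[dict],
    condition_labels: list[str] | None = None,
) -> tuple[list[Signature], Dendrogram]:
    """Analyze a movie tree end to end and write all result artifacts.

    ``conditions`` are metadata selectors (one signature each);
    ``config.baseline`` names the Mock-treated control pooled at the
    proximal readout. Writes the two mined tables, z_scores.csv, the
    dendrogram merge table and a Newick tree under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analyze_tree(root, config)
    tracks, morphology = mine_tree(root, config, out_dir=out_dir)
    labels = condition_labels or [None] * len(conditions)
    signatures = [
        assemble_signature(
            tracks,
            morphology,
            condition=cond,
            baseline=config.baseline,
            label=label,
            significance_band=config.significance_band,
            welch=config.welch,
        )
        for cond, label in zip(conditions, labels)
    ]
    write_zscores_csv(signatures, out_dir / "z_scores.csv")
    dist = signature_distance_matrix(signatures, config.cluster_subset)
    dendrogram = average_linkage(dist, [s.label for s in signatures])
    write_merge_table(dendrogram, out_dir / "dendrogram_merges.csv")
    (out_dir / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")
    return signatures, dendrogram
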