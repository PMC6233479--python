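"""Standard synthetic validation scenarios and ground-truth matching.

Two scenarios are provided:

* ``tracking_recovery`` — one small movie of non-crossing organelles
  (half stationary, half moving at constant speed) to quantify how well
  detection + linking recover the known tracks: recovery rate, relative
  mean-speed error, and direction-classification accuracy.
* ``slowdown_experiment`` — a four-condition experiment (control and a
  distal-slowdown phenotype, two replicate conditions each) exercising
  the whole pipeline: the slowdown should print strongly negative
  distal speed Z-scores, near-zero proximal ones, and a dendrogram in
  which the two slowdown replicates merge before joining any control.

Scenario organelles are 0.8 um (lysosome-sized) so that twenty
non-crossing lanes fit a 128 x 64 px field without the detector's
minimum-separation suppression; the detector scale is matched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ohp.cluster import Dendrogram, average_linkage, signature_distance_matrix
from ohp.config import PipelineConfig
from ohp.core import Calibration
from ohp.detect import DetectionParams, detect_spots
from ohp.pipeline import SyntheticCondition, mine_tree, run_full_pipeline, simulate_experiment
from ohp.signature import Signature
from ohp.simulate import AppearanceModel, GroundTruth, MotilityModel, simulate_movie
from ohp.track import Track, TrackingParams, link_tracks

__all__ = [
    "BENCHMARK_GEOMETRY",
    "benchmark_motility",
    "benchmark_appearance",
    "benchmark_config",
    "match_tracks",
    "TrackingRecovery",
    "tracking_recovery",
    "SLOWDOWN_CONDITIONS",
    "slowdown_experiment",
]

#: (T, H, W) of the small validation movies.
BENCHMARK_GEOMETRY = (60, 128, 64)

BENCHMARK_DIAMETER_UM = 0.8


def benchmark_motility(n_organelles: int = 20) -> MotilityModel:
    """Non-crossing constant-velocity population: half stationary, half
    moving without pauses (the linear-motion tracker's home ground)."""
    return MotilityModel(
        n_organelles=n_organelles,
        stationary_fraction=0.5,
        anterograde_fraction_of_moving=0.5,
        speed_mean_um_s=0.8,
        speed_sd_um_s=0.2,
        jitter_sd_um=0.02,
        pause_probability=0.0,
    )


def benchmark_appearance() -> AppearanceModel:
    # peak/background of 4000/400 with 40-count noise: SNR 90 >> 10.
    return AppearanceModel(diameter_um=BENCHMARK_DIAMETER_UM)


def benchmark_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        detection=DetectionParams(
            estimated_diameter_um=BENCHMARK_DIAMETER_UM, quality_threshold=20.0
        ),
        seed=seed,
    )


def match_tracks(
    ground_truth: GroundTruth,
    tracks: list[Track],
    tolerance_um: float = 0.5,
) -> dict[int, Track]:
    """Match each ground-truth organelle to the best recovered track.

    A track matches an organelle when the median distance between its
    spots and the organelle's true positions at those frames is below
    ``tolerance_um`` and at least half the track's spots have a valid
    true position; among matches the one covering the most frames wins.
    """
    matched: dict[int, Track] = {}
    for org in ground_truth.organelles:
        best: tuple[int, Track] | None = None
        for tr in tracks:
            dists = []
            for s in tr.spots:
                if s.frame >= len(org.positions_um):
                    continue
                x, y = org.positions_um[s.frame]
                if np.isnan(x):
                    continue
                dists.append(float(np.hypot(s.x_um - x, s.y_um - y)))
            if (
                dists
                and np.median(dists) < tolerance_um
                and len(dists) >= 0.5 * len(tr.spots)
            ):
                if best is None or len(dists) > best[0]:
                    best = (len(dists), tr)
        if best is not None:
            matched[org.id] = best[1]
    return matched


@dataclass(frozen=True)
class TrackingRecovery:
    n_ground_truth: int
    n_recovered: int
    speed_errors: tuple[float, ...]  # relative, moving organelles only
    n_direction_checked: int
    n_direction_correct: int

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_ground_truth

    @property
    def mean_speed_error(self) -> float:
        return float(np.mean(self.speed_errors)) if self.speed_errors else 0.0

    @property
    def direction_accuracy(self) -> float:
        if self.n_direction_checked == 0:
            return 1.0
        return self.n_direction_correct / self.n_direction_checked


def tracking_recovery(
    seed: int = 0,
    n_organelles: int = 20,
    geometry: tuple[int, int, int] = BENCHMARK_GEOMETRY,
    calibration: Calibration | None = None,
) -> TrackingRecovery:
    """Simulate one benchmark movie, run detection + tracking, and score
    recovery against the ground truth.

    Direction accuracy is scored on moving organelles whose true net x
    displacement exceeds 3x the stationary jitter SD.
    """
    calibration = calibration or Calibration()
    motility = benchmark_motility(n_organelles)
    config = benchmark_config(seed)
    movie, truth = simulate_movie(
        motility, benchmark_appearance(), geometry, calibration, seed=seed
    )
    spots = detect_spots(movie, config.detection)
    tracks = link_tracks(spots, config.tracking, calibration)
    matched = match_tracks(truth, tracks)
    speed_errors = []
    n_dir = n_dir_ok = 0
    for org in truth.organelles:
        tr = matched.get(org.id)
        if tr is None or org.direction == "stationary":
            continue
        speed_errors.append(
            abs(tr.features.mean_speed_um_s - org.speed_um_s) / org.speed_um_s
        )
        if abs(org.net_x_displacement_um()) > 3 * motility.jitter_sd_um:
            n_dir += 1
            n_dir_ok += int(tr.features.direction == org.direction)
    return TrackingRecovery(
        n_ground_truth=len(truth),
        n_recovered=len(matched),
        speed_errors=tuple(speed_errors),
        n_direction_checked=n_dir,
        n_direction_correct=n_dir_ok,
    )


#: Four-condition disease-discrimination scenario: two control replicate
#: conditions and two distal-slowdown replicates (moving speed halved at
#: the distal readout only).
SLOWDOWN_CONDITIONS = (
    SyntheticCondition(treatment="Mock", disease="Ctrl"),
    SyntheticCondition(treatment="Mock", disease="CtrlRep"),
    SyntheticCondition(treatment="Mock", disease="Slow", distal_speed_factor=0.5),
    SyntheticCondition(treatment="Mock", disease="SlowRep", distal_speed_factor=0.5),
)


def slowdown_experiment(
    work_dir: str | Path,
    seed: int = 0,
    movies_per_condition: int = 3,
    n_organelles: int = 20,
) -> tuple[list[Signature], Dendrogram]:
    """Run the four-condition slowdown scenario end to end.

    Simulates the tree under ``work_dir``, analyzes every movie, mines
    and filters, assembles the four signatures against the Ctrl-Mock
    proximal baseline, and clusters them. Returns (signatures,
    dendrogram) with signature labels equal to the disease fields.
    """
    work_dir = Path(work_dir)
    config = benchmark_config(seed)
    simulate_experiment(
        work_dir / "tree",
        list(SLOWDOWN_CONDITIONS),
        config,
        motility=benchmark_motility(n_organelles),
        appearance=benchmark_appearance(),
        geometry=BENCHMARK_GEOMETRY,
        movies_per_condition=movies_per_condition,
        seed=seed,
    )
    selectors = [{"treatment": "Mock", "disease": c.disease} for c in SLOWDOWN_CONDITIONS]
    return run_full_pipeline(
        work_dir / "tree",
        config,
        work_dir / "results",
        conditions=selectors,
        condition_labels=[c.disease for c in SLOWDOWN_CONDITIONS],
    )
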