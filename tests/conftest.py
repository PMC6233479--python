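import numpy as np
import pytest

from ohp.benchmark import (
    benchmark_appearance,
    benchmark_config,
    benchmark_motility,
    BENCHMARK_GEOMETRY,
    slowdown_experiment,
    tracking_recovery,
)
from ohp.core import Calibration
from ohp.detect import detect_spots
from ohp.simulate import simulate_movie
from ohp.track import link_tracks


@pytest.fixture(scope="session")
def cal() -> Calibration:
    return Calibration()


@pytest.fixture(scope="session")
def benchmark_run(cal):
    """One benchmark movie fully detected and tracked (seed 0)."""
    config = benchmark_config(seed=0)
    movie, truth = simulate_movie(
        benchmark_motility(), benchmark_appearance(), BENCHMARK_GEOMETRY, cal, seed=0
    )
    spots = detect_spots(movie, config.detection)
    tracks = link_tracks(spots, config.tracking, cal)
    return movie, truth, spots, tracks


@pytest.fixture(scope="session")
def recovery0():
    return tracking_recovery(seed=0)


@pytest.fixture(scope="session")
def slowdown_results(tmp_path_factory):
    """Signatures and dendrogram of the four-condition slowdown scenario."""
    work = tmp_path_factory.mktemp("slowdown")
    return slowdown_experiment(work, seed=1)
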