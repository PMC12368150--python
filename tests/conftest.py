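import numpy as np
import pytest

from myxostream import (
    SwarmConfig,
    ThresholdSet,
    equalize,
    make_windows,
    persistence_stack,
    simulate_swarm,
    stream_series,
)
from myxostream.pipeline import optimize_thresholds
from myxostream.synthetic import StreamLane


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def two_lane_config(seed: int = 3) -> SwarmConfig:
    """A small two-lane streams movie: slow dispersed phase until frame 40,
    then two horizontal lanes active to the end of the movie."""
    return SwarmConfig(
        image_size=200,
        n_frames=100,
        n_cells=120,
        scenario="streams",
        stream_lanes=[
            StreamLane([(0, 50), (200, 50)], 24, 40, 99),
            StreamLane([(0, 130), (200, 130)], 24, 40, 99),
        ],
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def streams_movie():
    return simulate_swarm(two_lane_config())


@pytest.fixture(scope="session")
def streams_pstack(streams_movie):
    return equalize(persistence_stack(streams_movie.stack))


@pytest.fixture(scope="session")
def optimized_thresholds(streams_pstack) -> ThresholdSet:
    # calibration frames from the stream phase (lane-active persistence frames)
    return optimize_thresholds(streams_pstack, [55, 70, 85])


@pytest.fixture(scope="session")
def streams_series_bundle(streams_movie, streams_pstack, optimized_thresholds):
    """Stream-mask series on the two-lane movie at a 10-min stride."""
    windows = make_windows(streams_pstack, 30, 10.0)
    series = stream_series(streams_pstack, windows, optimized_thresholds)
    return streams_movie, streams_pstack, windows, series
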