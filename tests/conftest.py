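import numpy as np
import pytest

from lamellikine import synthetic_data as sd
from lamellikine import track_metrics as tm


@pytest.fixture
def straight_track():
    """Straight line at 1 um/min, one frame every 5 min, 48 frames."""
    times = np.arange(48) * 5.0
    positions = np.column_stack([times * 1.0, np.zeros(48)])
    return tm.Track("straight", times, positions)


@pytest.fixture
def stationary_track():
    times = np.arange(20) * 5.0
    return tm.Track("still", times, np.zeros((20, 2)))


@pytest.fixture(scope="session")
def sector_movie():
    """90-degree sector, 20 um radius, protrusion step >= 2 px/frame."""
    masks, truth = sd.synth_edge_movie(
        90.0, 1.0, 0.5, shape=(256, 256), pixel_size=0.2,
        frame_interval=30.0, n_frames=6, radius=20.0,
    )
    return masks, truth


@pytest.fixture(scope="session")
def flow_movie():
    params = sd.FlowMovieParams(
        shape=(128, 128), pixel_size=0.05, frame_interval=3.22,
        n_frames=12, flow_speed=1.5, noise_sd=0.02, seed=7,
    )
    return sd.synth_flow_movie(params) + (params,)
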