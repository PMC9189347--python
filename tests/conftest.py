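import numpy as np
import pytest

from confinetrack import (CellSpec, NoiseParams, constriction_channel,
                          simulate_constriction_movie, simulate_straight_movie,
                          straight_channel)


@pytest.fixture(scope="session")
def small_straight():
    """3 steadily crawling cells, 20 frames, noise-free."""
    geom = straight_channel(n_lanes=3, length_um=200)
    cells = [CellSpec(mode="A1", speed_um_per_min=0.9, switch_prob=0.0)
             for _ in range(3)]
    stack, gt = simulate_straight_movie(geom, cells, 20, NoiseParams(seed=1))
    return geom, stack, gt


@pytest.fixture(scope="session")
def small_constriction():
    """3 fast cells with scripted transit delays 5/7/10 frames."""
    geom = constriction_channel(n_lanes=3, length_um=320)
    cells = [CellSpec(mode="A2", speed_um_per_min=3.0, switch_prob=0.0,
                      radius_um=4.0) for _ in range(3)]
    stack, gt = simulate_constriction_movie(geom, cells, 90, NoiseParams(seed=3),
                                            [5, 7, 10])
    return geom, stack, gt


class FakeTrack:
    """Minimal track-like object for metric and passage tests."""

    def __init__(self, frames, x, y, track_id=0):
        self.track_id = track_id
        self.frames = np.asarray(frames)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)


@pytest.fixture
def make_track():
    return FakeTrack
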