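import numpy as np
import pytest

import fishstim as fs


@pytest.fixture(scope="session")
def short_track() -> fs.MidlineTrack:
    """5-s seeded swimmer track shared by fast tests."""
    return fs.simulate_swimmer(fs.SwimmerParams(seed=7, duration=5.0))


@pytest.fixture(scope="session")
def minute_track() -> fs.MidlineTrack:
    """Full one-minute track at 60 fps (3600 frames)."""
    return fs.simulate_swimmer(fs.SwimmerParams(seed=11, duration=60.0))


@pytest.fixture(scope="session")
def short_anim(short_track) -> fs.SkeletalAnimation:
    return fs.track_to_animation(short_track)


@pytest.fixture()
def rigid_straight_track() -> fs.MidlineTrack:
    """A straight fish translating along +x: all segment vectors (1,0,0)."""
    n_frames, n_points = 50, 6
    pts = np.zeros((n_frames, n_points, 3))
    base = np.arange(n_points)[::-1] * 6.0  # head leads, tail 30 mm behind
    for f in range(n_frames):
        pts[f, :, 0] = base + 2.0 * f
        pts[f, :, 2] = 40.0
    return fs.MidlineTrack(points=pts, fps=60.0)
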