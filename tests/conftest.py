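import numpy as np
import pytest

from pbmstudy import behavior as bh
from pbmstudy import histology as hi


@pytest.fixture
def nort_arena():
    return bh.nort_arena()


@pytest.fixture
def ymaze_arena():
    return bh.ymaze_arena()


@pytest.fixture
def mwm():
    return bh.mwm_arena()


@pytest.fixture
def mwm_probe():
    return bh.mwm_arena(probe=True)


@pytest.fixture
def full_region():
    def make(shape, pixel_size_um=0.6):
        return hi.RegionAnnotation.full_frame(shape, pixel_size_um=pixel_size_um)

    return make


def straight_trajectory(start, end, speed_cm_s, frame_rate_hz, pad_to_s=None):
    """Body-center moves in a straight line at constant speed; nose/head
    lie ahead along the direction of travel."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    dist = np.hypot(*(end - start))
    n_move = max(int(round(dist / speed_cm_s * frame_rate_hz)), 1)
    t_end = n_move / frame_rate_hz
    total_s = max(pad_to_s or t_end, t_end)
    n = int(round(total_s * frame_rate_hz)) + 1
    time_s = np.arange(n) / frame_rate_hz
    frac = np.clip(time_s / t_end, 0, 1)
    body = start + frac[:, None] * (end - start)
    u = (end - start) / max(dist, 1e-9)
    return bh.Trajectory(time_s, body + 2.5 * u, body + 1.5 * u, body)
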