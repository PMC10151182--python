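import numpy as np
import pytest

from gridtheta.navio import TrajectoryLog


def make_traj(segments, rate=10.0, block_id="b0", start=(50.0, 50.0), speed=1.0):
    """Build a TrajectoryLog from (moving, duration_s, heading_deg) segments.

    Movement advances at ``speed`` vm/s along the given heading; immobile
    segments hold position (heading still defined).
    """
    dt = 1.0 / rate
    t, x, y, heading, moving = [], [], [], [], []
    px, py = start
    clock = 0.0
    for mv, dur, hd in segments:
        n = int(round(dur * rate))
        for _ in range(n):
            if mv:
                px += speed * dt * np.sin(np.deg2rad(hd))
                py += speed * dt * np.cos(np.deg2rad(hd))
            t.append(clock)
            x.append(px)
            y.append(py)
            heading.append(hd % 360.0)
            moving.append(mv)
            clock += dt
    n = len(t)
    return TrajectoryLog(np.array(t), np.array(x), np.array(y),
                         np.array(heading), np.array(moving),
                         np.full(n, block_id))


@pytest.fixture
def schedule_traj():
    """Ten 2 s bouts alternating with 2 s pauses over 40 s (50 Hz)."""
    segs = []
    for i in range(10):
        segs.append((False, 2.0, 30.0 * i))
        segs.append((True, 2.0, 30.0 * i))
    return make_traj(segs, rate=50.0)
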