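import numpy as np
import pytest

from invadex import synthgen as sg


@pytest.fixture
def small_config():
    return sg.SimulationConfig(seed=7, window=(0.0, 0.0, 100.0, 100.0),
                               pixel_size=0.5)


@pytest.fixture
def tissue_config():
    return sg.SimulationConfig(seed=11, window=(0.0, 0.0, 300.0, 300.0),
                               pixel_size=0.5)


def brute_force_nnd(points: np.ndarray):
    """All-pairs O(n^2) nearest-neighbor oracle; ties -> lowest index."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = []
    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        dmin = d.min()
        j = int(np.flatnonzero(d == dmin)[0])
        out.append((float(dmin), j))
    return out
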