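import numpy as np
import pandas as pd
import pytest

from protonflux import CellFrame, PhysicalParams, ProbeFrame


@pytest.fixture
def params():
    return PhysicalParams()


def make_cell_frame(positions, frame_index=0, time_min=0.0, ids=None):
    positions = np.atleast_2d(np.asarray(positions, float))
    ids = ids or [f"c{i}" for i in range(len(positions))]
    return CellFrame(frame_index, time_min, pd.DataFrame({
        "cell_id": ids, "x_um": positions[:, 0], "y_um": positions[:, 1],
        "cell_type": "unknown",
    }))


def make_probe_frame(positions, ph, sigma=0.02, frame_index=0, time_min=0.0):
    positions = np.atleast_2d(np.asarray(positions, float))
    ph = np.broadcast_to(np.asarray(ph, float), (len(positions),))
    sigma = np.broadcast_to(np.asarray(sigma, float), (len(positions),))
    return ProbeFrame(frame_index, time_min, pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(positions))],
        "x_um": positions[:, 0], "y_um": positions[:, 1],
        "pH": ph, "sigma": sigma,
    }))
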