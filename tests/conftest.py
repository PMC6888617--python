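import numpy as np
import pytest

from uwbvitals import RadarCube
from uwbvitals.study import calibrate_from_simulated_humans


def make_cube(data, rate=20.0, spacing=0.01, start=0.0, stage="dc_removed"):
    """Small hand-built cube for unit tests."""
    return RadarCube(
        amplitudes=np.asarray(data, dtype=float),
        range_bin_spacing=spacing,
        slow_time_rate=rate,
        start_range=start,
        stage=stage,
    )


@pytest.fixture(scope="session")
def human_standard():
    """Energy standard calibrated once from five simulated human recordings."""
    return calibrate_from_simulated_humans(n_subjects=5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
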