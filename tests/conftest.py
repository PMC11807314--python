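import numpy as np
import pandas as pd
import pytest

from timerflow import CellMatrix, KineticsConfig, MeasurementConfig, timer_transform_batch
from timerflow.synthetic import BLUE_CHANNEL, RED_CHANNEL, simulate_timecourse


@pytest.fixture(scope="session")
def small_timecourse(tmp_path_factory):
    """A small synthetic time course: 5 timepoints x 1 replicate, 400 cells
    per sample, plus the negative control. Returns (manifest, out_dir)."""
    out = tmp_path_factory.mktemp("timecourse")
    kin = KineticsConfig()
    meas = MeasurementConfig(n_cells=400, seed=11)
    manifest = simulate_timecourse(kin, meas, [0, 4, 8, 16, 24], 1, out)
    return manifest, out


@pytest.fixture(scope="session")
def small_result(small_timecourse):
    manifest, _ = small_timecourse
    return timer_transform_batch(manifest)


def toy_matrix(blue, red, sample_id="toy", extra=None):
    data = {BLUE_CHANNEL: np.asarray(blue, dtype=float),
            RED_CHANNEL: np.asarray(red, dtype=float)}
    if extra:
        data.update(extra)
    return CellMatrix(sample_id, pd.DataFrame(data))
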