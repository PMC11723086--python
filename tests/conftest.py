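import numpy as np
import pytest

from kernelid.decay import DEFAULT_CONFIG, AcquisitionGrid
from kernelid.simulate import default_variety_params


@pytest.fixture(scope="session")
def grid() -> AcquisitionGrid:
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def variety_params(grid):
    """Calibrated generator parameters for all 11 varieties (cached)."""
    return default_variety_params(grid, DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full 330-sample pipeline run shared by the end-to-end tests."""
    from kernelid.pipeline import run_pipeline

    return run_pipeline(seed=0, n_per_variety=30)


def mono_exponential(grid: AcquisitionGrid, amplitude: float, tau: float):
    from kernelid.decay import DecayCurve

    t = grid.times
    return DecayCurve(time=t, signal=amplitude * np.exp(-t / tau), sample_id="mono")
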