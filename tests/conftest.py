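import numpy as np
import pytest

from smstoich import FilterParams, SimulationConfig
from smstoich.steps import TraceRecord


@pytest.fixture
def filter_params() -> FilterParams:
    return FilterParams()


@pytest.fixture
def default_sim() -> SimulationConfig:
    return SimulationConfig()


def make_trace(intensity, cy3=100.0, frame_rate=5.0, spot_id=0, condition=None, edge=False):
    intensity = np.asarray(intensity, dtype=float)
    t = np.arange(intensity.size) / frame_rate
    return TraceRecord(
        spot_id=spot_id,
        t=t,
        intensity=intensity,
        cy3_intensity=cy3,
        condition_m=condition,
        edge_clipped=edge,
    )


@pytest.fixture
def staircase():
    """Noiseless 4-step unit staircase with long plateaus."""
    levels = [4.0, 3.0, 2.0, 1.0, 0.0]
    return make_trace(np.repeat(levels, 60))
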