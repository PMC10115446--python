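import numpy as np
import pytest

from barsaccade import synthgen
from barsaccade.types import ModelParams


@pytest.fixture(scope="session")
def bar_112() -> "synthgen.BarTrajectory":
    """The study's standard stimulus: 112.5 deg/s CW for 25 s at 200 Hz."""
    return synthgen.gen_bar_trajectory(112.5, 25.0, direction=1)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
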