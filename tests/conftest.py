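import numpy as np
import pytest

from vinespec.pipeline import RunConfig, run_all
from vinespec.sensors import SENSOR_1, SENSOR_2


@pytest.fixture(scope="session")
def demo_run():
    """One full end-to-end run of the default campaign (seed 0), shared by
    every test that needs a realistic fitted model or sample table."""
    return run_all(RunConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=[SENSOR_1, SENSOR_2], ids=["sensor1", "sensor2"])
def sensor(request):
    return request.param
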