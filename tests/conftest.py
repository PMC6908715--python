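import numpy as np
import pytest

from bvamecg.dynamics import locate_attractor_cycle
from bvamecg.model import ModelParams


@pytest.fixture(scope="session")
def params_h3() -> ModelParams:
    return ModelParams(H=3.0)


@pytest.fixture(scope="session")
def params_h7() -> ModelParams:
    return ModelParams(H=7.0)


@pytest.fixture(scope="session")
def cycle_h7(params_h7):
    """The attracting limit cycle at H=7, converged once per session."""
    return locate_attractor_cycle(params_h7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
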