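import datetime

import numpy as np
import pytest

from deicer_biofilm.config import ScenarioConfig


@pytest.fixture
def config() -> ScenarioConfig:
    return ScenarioConfig(seed=0)


@pytest.fixture
def small_config() -> ScenarioConfig:
    """Single-season scenario: keeps whole-pipeline tests fast."""
    return ScenarioConfig(
        seed=0,
        start=datetime.date(2009, 12, 1),
        end=datetime.date(2010, 6, 30),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
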