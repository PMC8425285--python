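import logging

import numpy as np
import pytest
from hypothesis import settings

from metabloom import pipeline, synth

logging.getLogger("metabloom").setLevel(logging.ERROR)

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_scenario():
    """The default 12-year synthetic monitoring scenario (fixed seed)."""
    return synth.generate_scenario(synth.ScenarioConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_tables(default_scenario):
    """Full analysis bundle computed from the default scenario."""
    res = default_scenario
    return pipeline.run_pipeline(res.profiles, None, res.hypsography)


@pytest.fixture(scope="session")
def truth(default_scenario):
    return default_scenario.truth_profiles.set_index("date")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
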