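import numpy as np
import pytest
from hypothesis import settings

from chromofiber import RunConfig, build_fiber, generate_tracks

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fiber():
    """The default 61-nucleosome solenoid fiber (built once per session)."""
    return build_fiber()


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(base_seed=101)


@pytest.fixture(scope="session")
def default_events(default_config):
    """One default synthetic track ensemble (1000 histories, fixed seed)."""
    import dataclasses

    params = dataclasses.replace(default_config.tracks, seed=101)
    return generate_tracks(params, default_config.envelope)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
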