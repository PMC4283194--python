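import logging
import os
import tempfile

# keep hypothesis' on-disk caches out of the repository
os.environ.setdefault("HYPOTHESIS_STORAGE_DIRECTORY",
                      os.path.join(tempfile.gettempdir(), "hypothesis"))

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cb1tacs.core import default_schedule
from cb1tacs.simulate import simulate_input

# the uniform-weight fallback warning is expected in tests that omit trues
logging.getLogger("cb1tacs").setLevel(logging.ERROR)

# deterministic property tests, no on-disk example database
settings.register_profile(
    "deterministic", derandomize=True, database=None,
    suppress_health_check=[HealthCheck.differing_executors])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def input_fn():
    """Deterministic default-shape input function."""
    return simulate_input()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
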