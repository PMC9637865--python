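import logging

import numpy as np
import pytest

from normdev import synthetic

# keep the clamp warnings of cross-validation folds out of test output
logging.getLogger("normdev.normative").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> synthetic.SimulatedCohort:
    """Default-condition cohort, small enough for fast unit tests."""
    return synthetic.generate_cohort(300, seed=12345)


@pytest.fixture(scope="session")
def medium_cohort() -> synthetic.SimulatedCohort:
    return synthetic.generate_cohort(2000, seed=2024)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
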