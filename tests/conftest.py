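import numpy as np
import pytest
from hypothesis import settings

from phytodiv import synthetic_data

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile():
    """The packaged three-accession default study profile."""
    return synthetic_data.default_profile()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220)
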