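import numpy as np
import pytest

from socmap.config import RunConfig
from socmap import pipeline, synth


@pytest.fixture(scope="session")
def default_session():
    """One full-scale synthetic session (137 clips, 768 retained volumes)."""
    return pipeline.build_session(0, RunConfig())


@pytest.fixture(scope="session")
def small_recovery():
    """A reduced cohort recovery run shared by end-to-end unit tests.

    Twelve subjects keep this fast; the planted effects are strong enough
    that hub recovery already succeeds at this scale.
    """
    return pipeline.run_recovery(0, n_subjects=12)


@pytest.fixture(scope="session")
def ground_truth():
    return synth.make_ground_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
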