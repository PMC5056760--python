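import pytest

from helpers import run_pipeline
from m6asite.synthetic import SyntheticConfig, null_config


@pytest.fixture(scope="session")
def strong_pipeline():
    """Full mature-mode pipeline on the strongly separable bundle.

    Session-scoped: the shuffle-based structure features dominate the
    cost, and several tests inspect different facets of the same run.
    """
    return run_pipeline(SyntheticConfig(seed=11), "mature", seed=11, grid=True)


@pytest.fixture(scope="session")
def null_pipeline():
    """Full-transcript-mode pipeline on the zero-signal bundle."""
    return run_pipeline(null_config(seed=0), "full", seed=0, C=8.0, gamma=2.0 ** -7)
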