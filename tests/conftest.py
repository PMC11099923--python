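import numpy as np
import pytest

from nmrdock.synthetic import GroundTruth, ground_truth_restraints, make_toy_complex


@pytest.fixture(scope="session")
def gt7() -> GroundTruth:
    """Default toy complex used across the suite (seed 7)."""
    return make_toy_complex(7)


@pytest.fixture(scope="session")
def truth_restraints7(gt7):
    return ground_truth_restraints(gt7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
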