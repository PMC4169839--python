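import warnings

import numpy as np
import pytest

from introscan.segments import build_design_matrix, build_segments
from introscan.simulate import make_ideal_population, make_overlapping_population


@pytest.fixture(autouse=True)
def _quiet_reml_boundary():
    """REML boundary hits are expected on weak-signal draws; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="REML profile optimum", category=RuntimeWarning
        )
        yield


@pytest.fixture(scope="session")
def pop1():
    """Ideal 9-line population, no recipient: Z = 2*I9."""
    return make_ideal_population()


@pytest.fixture(scope="session")
def pop1_trial():
    """Ideal population with the recipient check line included."""
    return make_ideal_population(include_recipient=True)


@pytest.fixture(scope="session")
def pop2():
    """Canonical overlapping-segment population (S > N)."""
    return make_overlapping_population()


@pytest.fixture(scope="session")
def smap1(pop1):
    return build_segments(pop1)


@pytest.fixture(scope="session")
def design1(smap1):
    return build_design_matrix(smap1)


@pytest.fixture(scope="session")
def smap2(pop2):
    return build_segments(pop2)


@pytest.fixture(scope="session")
def design2(smap2):
    return build_design_matrix(smap2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
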