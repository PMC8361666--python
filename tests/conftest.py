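import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from metablup import StudySet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_pair():
    """Two balanced studies with a hand-solvable tau^2 of 1.5."""
    return StudySet(y=[0.0, 2.0], v=[0.5, 0.5])


@pytest.fixture
def toy_five():
    """Five-study set with unequal variances."""
    return StudySet(
        y=[0.10, -0.30, 0.55, 0.20, -0.05],
        v=[0.08, 0.20, 0.12, 0.35, 0.15],
    )


def study_sets(min_n=2, max_n=10):
    """Hypothesis strategy for random valid StudySets."""

    def build(n):
        y = hnp.arrays(
            float,
            n,
            elements=st.floats(-3.0, 3.0, allow_nan=False),
        )
        v = hnp.arrays(
            float,
            n,
            elements=st.floats(0.05, 2.0, allow_nan=False),
        )
        return st.tuples(y, v).map(lambda t: StudySet(y=t[0], v=t[1]))

    return st.integers(min_n, max_n).flatmap(build)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
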