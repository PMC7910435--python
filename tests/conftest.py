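import math

import numpy as np
import pytest

from postlearn.model import AgentParams, PostTimeline
from postlearn.simulate import (
    CohortSpec,
    STRONG_LEARNING_DISTRIBUTIONS,
    generate_cohort,
)


@pytest.fixture(scope="session")
def null_timeline():
    """Ten-post timeline with known latencies for closed-form checks."""
    tau = np.array([10.0, 20.0, 30.0, 15.0, 25.0, 20.0, 18.0, 22.0, 20.0])
    ts = np.concatenate([[0.0], np.cumsum(tau)])
    return PostTimeline("u-null", ts, np.full(10, 3.0))


@pytest.fixture(scope="session")
def small_null_cohort():
    return generate_cohort(
        CohortSpec(n_users=30, posts_per_user=80, variant="null_no_learning",
                   seed=101)
    )


@pytest.fixture(scope="session")
def small_learning_cohort():
    """Clearly-learning agents (upper stable learning-rate band)."""
    return generate_cohort(
        CohortSpec(n_users=30, posts_per_user=150,
                   param_distributions=dict(STRONG_LEARNING_DISTRIBUTIONS),
                   seed=102)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
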