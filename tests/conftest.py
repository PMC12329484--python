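import numpy as np
import pandas as pd
import pytest

from allomem import CohortConfig, simulate_cohort
from allomem.pipeline import score_response_table


SMALL_COHORT = CohortConfig(
    n_subjects=8,
    runs=3,
    blocks_per_run=5,
    n_environments=6,
    seed=42,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic session (8 subjects, 15 trials each)."""
    return simulate_cohort(SMALL_COHORT)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    """Per-trial scores for the small cohort (no failure flags applied)."""
    truths = {e.env_id: e.truth for e in small_cohort.environments}
    return score_response_table(small_cohort.responses, truths)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pattern(rng, n=5, extent=4.0, labels=None):
    pts = rng.uniform(-extent, extent, size=(n, 2))
    labels = labels or [f"obj{i + 1}" for i in range(n)]
    from allomem import PositionalPattern

    return PositionalPattern(pts, labels)
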