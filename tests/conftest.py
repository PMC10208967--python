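import numpy as np
import pytest

from star import CohortConfig, IntakeTable, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full event-level simulated cohort under the packaged defaults."""
    return simulate_cohort(CohortConfig(seed=0), include_events=True)


@pytest.fixture(scope="session")
def fast_cohort():
    """Summary-only simulated cohort (no event rendering)."""
    return simulate_cohort(CohortConfig(seed=0), include_events=False)


@pytest.fixture
def toy_table():
    """Three-subject cohort with one forced Compulsive drinker.

    Full-cohort labels: A Low, B Compulsive, C High (hand-derived).
    """
    return IntakeTable(
        alcohol={"A": [1.0], "B": [2.0], "C": [3.0]},
        quinine={"A": [0.1], "B": [1.0], "C": [0.4]},
    )


def random_table(rng: np.random.Generator, n: int, n_sessions=(3, 4)) -> IntakeTable:
    """Random positive intake table for property tests."""
    subjects = [f"s{i:03d}" for i in range(n)]
    return IntakeTable(
        alcohol={s: rng.gamma(4.0, 0.3, size=n_sessions[0]) for s in subjects},
        quinine={s: rng.gamma(2.0, 0.3, size=n_sessions[1]) for s in subjects},
    )
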