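import pandas as pd
import pytest

from heatadapt import (
    GeneratorConfig,
    PUBLISHED_RULES,
    compute_deltas,
    generate_cohort,
    make_fixture_observations,
)


@pytest.fixture(scope="session")
def cohort_default():
    """A default-parameter cohort (25 participants, seed 7)."""
    return generate_cohort(GeneratorConfig(n_participants=25, seed=7))


@pytest.fixture(scope="session")
def observations_default(cohort_default):
    return compute_deltas(cohort_default)


@pytest.fixture(scope="session")
def fixture_obs():
    """The deterministic 75-observation reference fixture."""
    return make_fixture_observations()


@pytest.fixture
def rules():
    return PUBLISHED_RULES


def make_observations(values, labels, variable="d_hr"):
    """Minimal observation frame for split-search tests."""
    n = len(values)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "induction": ["HAz"] * n,
            "d_hr": 0.0,
            "d_sr": 0.0,
            "d_ts": 0.0,
            "improved": list(labels),
        }
    ).assign(**{variable: list(values)})
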