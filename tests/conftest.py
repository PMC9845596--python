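import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def older_config():
    from simscore.cohort import default_config

    return default_config("older", seed=11)


@pytest.fixture(scope="session")
def plain_older_config():
    """Older-group defaults with dysglycemia induction and therapy sampling
    switched off, for tests of the copula machinery itself."""
    from simscore.cohort import default_config

    cfg = default_config("older", n=10_000, seed=20_001)
    return dataclasses.replace(
        cfg,
        ifg_fraction=0.0,
        igt_fraction=0.0,
        dm_fraction=0.0,
        lipid_therapy_fraction=0.0,
        antihypertensive_fraction=0.0,
    )


@pytest.fixture(scope="session")
def scored_cohort():
    """A small two-group scored and classified cohort for analysis tests."""
    from simscore.classify import classify_dataframe
    from simscore.pipeline import simulate_study_cohort
    from simscore.scores import score_dataframe

    df = simulate_study_cohort(seed=5, groups=[
        {"age_group": "young", "n": 150},
        {"age_group": "older", "n": 250},
    ])
    return classify_dataframe(score_dataframe(df))
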