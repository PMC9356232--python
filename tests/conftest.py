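import pytest

from lmswell.pipeline import PipelineConfig, run_pipeline
from lmswell.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Full cohort (events included) used by feature and pipeline tests."""
    return generate_cohort(default_config(n_students=150, seed=11))


@pytest.fixture(scope="session")
def survey_cohort():
    """Large survey-only cohort for prevalence and classification checks."""
    return generate_cohort(default_config(n_students=2000, seed=42), with_events=False)


@pytest.fixture(scope="session")
def bundle(small_cohort):
    cfg = PipelineConfig(
        synthetic=True, cohort=default_config(n_students=150, seed=11), seed=11
    )
    return run_pipeline(cfg)
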