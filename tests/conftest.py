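import pytest
from hypothesis import settings

from colocea import Pipeline, Scenario, default_config
from colocea.cea import interval_grid, recommend
from colocea.observation import ADENOMA_FINDINGS
from colocea.oracle import simulate_patients

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def pipeline(config):
    return Pipeline(config)


@pytest.fixture(scope="session")
def life_model(pipeline):
    return pipeline.life_model


@pytest.fixture(scope="session")
def age50_table(pipeline):
    """Interval/ICER grid at screening age 50, all findings combined."""
    return interval_grid(pipeline, 50.0)


@pytest.fixture(scope="session")
def strata_outcomes(pipeline):
    """Recommendation per adenoma finding stratum at age 50, $100k/QALY."""
    return {
        f: recommend(pipeline, screen_age=50.0, finding=f, threshold=100_000.0)
        for f in ADENOMA_FINDINGS
    }


@pytest.fixture(scope="session")
def micro_full(config, pipeline):
    """One large microsimulation of the default scenario (screen at 50,
    follow-up at 58), shared by the observation and equivalence checks."""
    scenario = Scenario(screen_age=50.0, follow_up_ages=(58.0,))
    return scenario, simulate_patients(
        200_000, scenario, config, seed=20_10, life_model=pipeline.life_model
    )
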