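import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import demsim as ds

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_params():
    """Default synthetic world (seed 1): Gompertz mortality with secular
    improvement, late-life-rising incidence, HR 2, deep birth cohorts."""
    return ds.synthesize_parameter_set(1)


@pytest.fixture(scope="session")
def small_run(synth_params):
    """A 20k-actor baseline run of the default synthetic world."""
    return ds.run_population(synth_params, n_actors=20_000, seed=7)


@pytest.fixture(scope="session")
def small_pop(synth_params):
    return ds.build_actor_seeds(
        synth_params.demography.cohorts, synth_params.demography.migration, 500, seed=5
    )
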