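import numpy as np
import pytest
from hypothesis import settings

from boswellia.cohort import CohortConfig, generate_cohort
from boswellia.model_core import ModelParams
from boswellia.simulator import GameConfig, simulate_experiment
from boswellia.survey import load_catalog, score_respondents

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def scored_cohort():
    """Default-size cohort (210, 42 groups) scored with SC indices."""
    cohort, assignment = generate_cohort(CohortConfig(seed=101))
    return score_respondents(cohort, on_degenerate="drop"), assignment


@pytest.fixture(scope="session")
def default_records(scored_cohort):
    """One full default simulation (calibrated mode)."""
    cohort, assignment = scored_cohort
    cfg = GameConfig(seed=202)
    return simulate_experiment(
        cohort, assignment, cfg, rng=np.random.default_rng(202)
    )
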