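import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from frailspan.endpoints import label_assessments
from frailspan.fgi import default_catalog, score_assessments
from frailspan.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """Both strains, 12 mice per group (84 mice), fixed seed."""
    config = CohortConfig(n_mice_per_group=12, seed=11)
    mice, assessments, truth = generate_cohort(config)
    return config, mice, assessments, truth


@pytest.fixture(scope="session")
def small_scored(small_cohort, catalog):
    _, mice, assessments, _ = small_cohort
    fgi = score_assessments(assessments, catalog)
    labels = label_assessments(assessments, mice)
    return mice, assessments, fgi, labels
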