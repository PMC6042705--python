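import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mtbn import LongitudinalCohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def build_cohort(panel, condition_names, demographics=None, schema=None):
    """Assemble a cohort from a raw panel array, defaulting to no demographics."""
    panel = np.asarray(panel)
    n = panel.shape[0]
    if schema is None:
        schema = {}
    if demographics is None:
        demographics = pd.DataFrame(index=range(n))
        demographics = demographics[[]]
    return LongitudinalCohort(
        patient_ids=tuple(f"P{i}" for i in range(n)),
        demographics=pd.DataFrame(demographics, columns=list(schema)),
        panel=panel,
        condition_names=tuple(condition_names),
        demographic_schema=schema,
    )


@pytest.fixture
def two_cond_cohort():
    """4 patients, 2 conditions, 2 years; X and Y perfectly coupled in year 1."""
    panel = np.array(
        [
            [[0, 0], [0, 0]],
            [[0, 0], [0, 1]],
            [[1, 1], [1, 0]],
            [[1, 1], [1, 1]],
        ]
    )
    return build_cohort(panel, ("X", "Y"))


@pytest.fixture
def small_schema():
    return {"gender": ("Male", "Female"), "age_group": ("18-30", "31+")}


@pytest.fixture
def small_marginals():
    return {"gender": (0.85, 0.15), "age_group": (0.6, 0.4)}
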