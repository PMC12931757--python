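import numpy as np
import pandas as pd
import pytest

from mafldpred.data_model import CohortTable, VariableSchema
from mafldpred.synthetic import CohortSimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_schema():
    """Three continuous features, one binary feature, binary target."""
    return [
        VariableSchema("x1", "continuous", "U", (-100.0, 100.0)),
        VariableSchema("x2", "continuous", "U", (-100.0, 100.0)),
        VariableSchema("x3", "continuous", "U", (-100.0, 100.0)),
        VariableSchema("b1", "binary", positive_label="yes"),
        VariableSchema("y", "binary", positive_label="case", role="target"),
    ]


def make_small_cohort(small_schema, n=200, seed=0, effect=1.0):
    """Gaussian features with a class shift of `effect` SD on x1."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    frame = pd.DataFrame(
        {
            "x1": rng.standard_normal(n) + effect * y,
            "x2": rng.standard_normal(n),
            "x3": rng.standard_normal(n),
            "b1": rng.integers(0, 2, n).astype(float),
            "y": y.astype(float),
        },
        index=pd.RangeIndex(n, name="record_id"),
    )
    return CohortTable(list(small_schema), frame)


@pytest.fixture
def small_cohort(small_schema):
    return make_small_cohort(small_schema)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Balanced synthetic cohort at the published calibration, n = 3654."""
    table, _ = generate_cohort(CohortSimConfig(n_records=3654, prevalence=0.5, seed=42))
    return table
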