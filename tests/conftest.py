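import numpy as np
import pandas as pd
import pytest

from cogsubtype import CohortConfig, CohortTable, VariableSchema


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A quick-to-generate cohort with the default planted structure."""
    return CohortConfig(n_per_group=(20, 20, 40), n_features=8, seed=3)


def make_table(values: dict, groups: list, kinds: dict | None = None,
               roles: dict | None = None) -> CohortTable:
    """Hand-build a CohortTable from column dict; NaN marks missing."""
    df = pd.DataFrame(values)
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="subject_id")
    schema = {
        c: VariableSchema(
            c,
            (kinds or {}).get(c, "continuous"),
            (roles or {}).get(c, "feature"),
        )
        for c in df.columns
    }
    group = pd.Series(groups, index=df.index, name="group")
    return CohortTable.from_values(df, group, schema)


@pytest.fixture
def make_cohort_table():
    return make_table
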