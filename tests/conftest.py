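import numpy as np
import pandas as pd
import pytest

from tempheno.synth import CohortSpec, generate_cohort


def make_events(rows):
    """Build an EventTable from (pid, days, domain, variable, value) tuples."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "days_before_anchor", "domain", "variable", "value"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-set matched cohort shared by read-only tests."""
    spec = CohortSpec(n_cases=50, seed=123)
    events, cohort, planted = generate_cohort(spec)
    return spec, events, cohort, planted


@pytest.fixture
def rng():
    return np.random.default_rng(0)
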