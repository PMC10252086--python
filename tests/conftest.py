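import numpy as np
import pandas as pd
import pytest

from stromasig import Cohort, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick default-structure cohort for classification tests."""
    cfg = SimConfig(n_samples=150, n_genes=300, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def discovery_pair():
    """Two independently drawn cohorts sharing one planted gene panel."""
    a = generate_cohort(SimConfig(n_samples=300, n_genes=800, seed=21))
    b = generate_cohort(SimConfig(n_samples=300, n_genes=800, seed=22))
    return a, b


def tiny_survival_fixture():
    """8 samples, distinct times, one binary-ish covariate, no ties."""
    times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
    events = np.array([1, 0, 1, 1, 0, 1, 1, 1], dtype=float)
    x = np.array([0.5, -1.2, 1.7, 0.3, -0.7, 2.1, -1.5, 0.9])
    return x, times, events


@pytest.fixture
def tiny_survival():
    return tiny_survival_fixture()


def make_cohort(expr: pd.DataFrame, times, events, name="fixture") -> Cohort:
    clinical = pd.DataFrame(
        {"os_time": np.asarray(times, dtype=float),
         "os_event": np.asarray(events, dtype=int)},
        index=pd.Index(expr.columns, name="sample_id"),
    )
    return Cohort(expression=expr, clinical=clinical, name=name)
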