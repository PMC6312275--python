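import numpy as np
import pandas as pd
import pytest

import clonecast as cc
from clonecast.schema import Attribute


@pytest.fixture(scope="session")
def fast_spec():
    """Elastic-net pipeline with the reduced hyperparameter search."""
    return cc.ModelSpec(enet=cc.FAST_ENET_CONFIG)


@pytest.fixture(scope="session")
def sim_cohort():
    """One default 21-patient synthetic cohort with ground truth."""
    return cc.simulate_cohort(cc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_schema():
    """Minimal hand-written schema: one binary, two continuous attributes."""
    return (
        Attribute("flag", "clinical", "binary", allow_missing=False),
        Attribute("dose", "tumor"),
        Attribute("level", "circulating"),
    )


@pytest.fixture()
def tiny_cohort(tiny_schema):
    """Five patients, complete data, hand-checkable values."""
    df = pd.DataFrame(
        {
            "flag": [0, 1, 0, 1, 1],
            "dose": [1.0, 2.0, 3.0, 4.0, 5.0],
            "level": [0.5, 0.0, 2.0, 1.0, 4.0],
            "expanded_clone_count": [0, 3, 9, 5, 2],
            "dcb": [0, 0, 1, 1, 0],
        },
        index=pd.Index([f"P{i}" for i in range(5)], name="patient_id"),
        dtype=float,
    )
    return cc.CohortTable(tiny_schema, df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
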