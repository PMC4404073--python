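import numpy as np
import pandas as pd
import pytest

from gwcommute import (
    SemiparametricSpec,
    KernelSpec,
    discretize_outcome,
)
from gwcommute.synthetic import ScenarioConfig, generate_cohort

LOCAL_TERMS = ("env_built", "env_socio", "perception")


@pytest.fixture(scope="session")
def cohort200():
    """Small stationary cohort shared by fast tests."""
    return generate_cohort(ScenarioConfig(n=200, seed=3))


@pytest.fixture(scope="session")
def cohort_design(cohort200):
    """(y, X_local, X_global, points) extracted once."""
    c = cohort200
    return (
        discretize_outcome(c.hours),
        c.env_design(),
        c.individual_design(),
        c.points,
    )


def make_spec(neighbor_count=100, family="bisquare", mode="adaptive",
              bandwidth_m=None, global_columns=None, **kw):
    kernel = (KernelSpec(family, "adaptive", neighbor_count=neighbor_count)
              if mode == "adaptive"
              else KernelSpec(family, "fixed", bandwidth_m=bandwidth_m))
    gc = tuple(global_columns) if global_columns is not None else (
        "age_c", "female", "educ_high", "parking_work", "transit_pass",
        "commute_tertile", "n_vehicles", "n_bikes")
    return SemiparametricSpec(LOCAL_TERMS, gc, kernel, **kw)


def pooled_design(X_local, X_global):
    return pd.concat(
        [pd.Series(1.0, index=X_local.index, name="Intercept"),
         X_local, X_global.reset_index(drop=True)],
        axis=1,
    )
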