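import warnings

import numpy as np
import pandas as pd
import pytest

import longexpo as le
from longexpo.cohort import Cohort


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def build_cohort(rows, outcomes, tv=(), baseline=None, scale="ln"):
    """Cohort from compact specs: rows = [(sid, visit, time_days, exposure, *tv)]."""
    cols = ["subject_id", "visit", "time_days", "exposure", *tv]
    data = pd.DataFrame(rows, columns=cols)
    base = pd.DataFrame(
        {"outcome": pd.Series(outcomes)},
        index=pd.Index(sorted(set(data["subject_id"])), name="subject_id"),
    )
    if baseline:
        for k, v in baseline.items():
            base[k] = v
    return Cohort(data=data, baseline=base, exposure_scale=scale,
                  tv_covariates=tuple(tv),
                  baseline_covariates=tuple(baseline or ()))


@pytest.fixture
def toy_cohort():
    """Three subjects with visit patterns {1,2}, {1,2,3}, {1}."""
    rows = [
        (1, 1, 70.0, 1.0), (1, 2, 140.0, 2.0),
        (2, 1, 65.0, 0.5), (2, 2, 130.0, 1.5), (2, 3, 200.0, 2.5),
        (3, 1, 80.0, 3.0),
    ]
    return build_cohort(rows, {1: 1, 2: 0, 3: 1}, scale="raw")


@pytest.fixture(scope="session")
def phthalate_ln_cohort():
    """One seeded phthalate-like cohort on the ln scale."""
    scenario = le.make_scenario("phthalate_like")
    cohort, truth = le.simulate_cohort(scenario, seed=42)
    return le.ln_transform(cohort), truth, scenario


@pytest.fixture(scope="session")
def balanced_ln_cohort():
    scenario = le.make_scenario("balanced_dense", n_subjects=300)
    cohort, truth = le.simulate_cohort(scenario, seed=7)
    return le.ln_transform(cohort), truth, scenario
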