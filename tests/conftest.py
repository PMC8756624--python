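"""Shared fixtures: small hand-built cohorts and incomplete-cohort helpers."""

import numpy as np
import pandas as pd
import pytest

from imputebench import (OUTCOME, TARGET, Allocation, IncompleteCohort,
                         MissingScenario, table2_profile)
from imputebench.cohort import CSV_COLUMNS

VOL_LO, VOL_HI = "<30 ml", ">=30 ml"


def toy_records(target, deep_coma=None, outcome=None, co_infection=None):
    """Build a legal cohort frame with given target values; unspecified
    variables are held at their first-listed category."""
    n = len(target)
    profile = table2_profile()
    data = {}
    for var in profile.variables:
        data[var.name] = [var.categories[0]] * n
    data[TARGET] = list(target)
    if deep_coma is not None:
        data["deep_coma"] = list(deep_coma)
    if co_infection is not None:
        data["co_infection"] = list(co_infection)
    data[OUTCOME] = list(outcome) if outcome is not None else [0] * n
    return pd.DataFrame(data)[list(CSV_COLUMNS)]


def make_incomplete(records, seed=0, mechanism="MCAR", proportion=0.1):
    """Wrap a frame whose target column already contains NA cells."""
    mask = records[TARGET].isna().to_numpy()
    scenario = MissingScenario(mechanism, proportion, seed)
    return IncompleteCohort(
        records=records.reset_index(drop=True),
        mask=mask,
        original_target=records[TARGET].copy(),
        scenario=scenario,
        allocation=Allocation(int(mask.sum()), None, None),
    )


@pytest.fixture(scope="session")
def profile():
    return table2_profile()


@pytest.fixture(scope="session")
def coupled_cohort():
    """Small stochastic cohort with predictor-target coupling."""
    from imputebench import DEFAULT_DEPENDENCE, generate_cohort

    return generate_cohort(table2_profile(), mode="stochastic",
                           dependence=DEFAULT_DEPENDENCE, seed=11,
                           group_sizes=(450, 150))
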