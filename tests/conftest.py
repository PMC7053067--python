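import dataclasses

import numpy as np
import pandas as pd
import pytest

import pdqmap as pm
from pdqmap.pipeline import map_and_value


@pytest.fixture(scope="session")
def ordinal_model():
    return pm.demo_coefficients("ordinal")


@pytest.fixture(scope="session")
def multinomial_model():
    return pm.demo_coefficients("multinomial")


@pytest.fixture(scope="session")
def uk_valueset():
    return pm.demo_value_set("uk")


@pytest.fixture(scope="session")
def fr_valueset():
    return pm.demo_value_set("fr")


@pytest.fixture(scope="session")
def default_design():
    return pm.TrialDesign(seed=7)


@pytest.fixture(scope="session")
def small_design():
    """A fast-to-generate design for structural tests."""
    return pm.TrialDesign(n_arm_a=12, n_arm_b=10, missing_case_rate=0.0, seed=3)


def si_change_between(df: pd.DataFrame, alpha: float = 0.05):
    """Between-arm t-tests on PDQ-39 summary-index change scores.

    Returns a list of ComparisonResult, one per follow-up visit, computed
    on complete cases.  Sign convention: estimate = mean change A - B.
    """
    work = df.copy()
    work["si"] = pm.summary_index(work)
    visits = sorted(work["visit_month"].unique())
    filtered, _ = pm.complete_cases(work, visits, value_col="si")
    changes = pm.change_from_baseline(filtered, value_col="si")
    results = []
    for visit, dv in changes.groupby("visit_month"):
        results.append(
            pm.between_group_test(
                dv.loc[dv["arm"] == "A", "change"],
                dv.loc[dv["arm"] == "B", "change"],
                visit=visit,
                family_alpha=alpha,
                n_tests=len(visits) - 1,
            )
        )
    return results


def utility_change_between(df: pd.DataFrame, model, valueset, alpha: float = 0.05):
    """Between-arm t-tests on mapped utilities' change scores."""
    mapped = map_and_value(df, model, valueset)
    visits = sorted(mapped["visit_month"].unique())
    filtered, _ = pm.complete_cases(mapped, visits)
    changes = pm.change_from_baseline(filtered)
    results = []
    for visit, dv in changes.groupby("visit_month"):
        results.append(
            pm.between_group_test(
                dv.loc[dv["arm"] == "A", "change"],
                dv.loc[dv["arm"] == "B", "change"],
                visit=visit,
                family_alpha=alpha,
                n_tests=len(visits) - 1,
            )
        )
    return results


def replicate_designs(design, n, base_seed):
    for r in range(n):
        yield dataclasses.replace(design, seed=base_seed + r)


@pytest.fixture(scope="session")
def si_between():
    return si_change_between


@pytest.fixture(scope="session")
def util_between():
    return utility_change_between
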