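import numpy as np
import pandas as pd
import pytest

from physupply.indicators import build_indicator_table
from physupply.model import (
    PARAMETER_COLUMNS,
    QUOTA_COLUMNS,
    ParameterTable,
    Scenario,
    StockState,
    simulate,
)
from physupply.synthetic import (
    SyntheticProfile,
    generate_parameters,
    generate_regions,
    generate_required,
    make_scenario,
)

VALIDATION_YEARS = [1998, 2000, 2002, 2004, 2006, 2008]


def make_parameter_table(
    regions=("A",), years=range(2000, 2041), **overrides
) -> ParameterTable:
    """Minimal all-zero parameter table with selective overrides —
    the workhorse for single-flow engine tests."""
    values = {c: 0.0 for c in PARAMETER_COLUMNS}
    values.update(overrides)
    rates = pd.DataFrame(
        {c: [values[c]] * len(list(years)) for c in PARAMETER_COLUMNS},
        index=pd.Index(list(years), name="year"),
    )
    n = len(regions)
    options = pd.Series([1.0 / n] * n, index=list(regions))
    return ParameterTable(rates=rates, smsa_option_rates=options)


def make_single_region_scenario(
    initial_physicians=1000.0,
    baseline=2000,
    horizon=2030,
    params: ParameterTable | None = None,
    **param_overrides,
) -> Scenario:
    params = params or make_parameter_table(**param_overrides)
    state = StockState(
        year=baseline,
        students=np.zeros((6, 2)),
        residents=np.zeros((2, 2)),
        physicians=pd.Series({"A": float(initial_physicians)}),
        physicians_external=0.0,
    )
    return Scenario(
        baseline_year=baseline,
        horizon_year=horizon,
        report_years=list(range(baseline, horizon + 1)),
        initial_state=state,
        parameters=params,
    )


@pytest.fixture(scope="session")
def profile():
    return SyntheticProfile(seed=1)


@pytest.fixture(scope="session")
def params(profile):
    return generate_parameters(profile)


@pytest.fixture(scope="session")
def scenario(profile, params):
    return make_scenario(profile, params)


@pytest.fixture(scope="session")
def trajectory(scenario):
    return simulate(scenario)


@pytest.fixture(scope="session")
def regions(profile):
    return generate_regions(profile)


@pytest.fixture(scope="session")
def required(profile, regions, scenario):
    return generate_required(profile, regions, scenario.initial_state)


@pytest.fixture(scope="session")
def indicators(trajectory, regions, required):
    return build_indicator_table(trajectory, regions, required, 1.0)
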